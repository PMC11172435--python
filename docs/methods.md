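# Methods

## Coordinates and containers

All coordinates are 0-based, half-open, relative to the first nucleotide
of the start codon; codon `i` covers nucleotides `[3i, 3i+3)`. Sequences
are canonicalized to the RNA alphabet (T read as U). FASTA records whose
length is not a positive multiple of 3, or that contain ambiguous bases,
are dropped with a logged count rather than masked: codon statistics must
be exact, and pseudocount-style repairs would distort small test
fixtures. Footprints are 5'-end counts keyed by (gene, position, read
length); positions may be negative (reads starting in the 5' UTR).
Read lengths partition into the 21-nt class {20, 21, 22} and the 28-nt
class {27, 28, 29, 30}; other lengths are retained in the container but
ignored by the analyses.

## Position weight matrices

`weight(pos, N) = log2(f_obs(pos, N) / f_exp(N))`, with `f_exp` the
pooled nucleotide frequency of the same ORF set over all positions
regardless of codon structure. Conditional (adjacency) PWMs tally only
codons whose 5' neighbour, within the same ORF, matches a reference codon
class; adjacency never crosses ORF boundaries. Where `f_obs` or `f_exp`
is zero the weight is reported as NaN and excluded from comparisons — no
pseudocounts. Correctness is cross-checked in the test suite against an
independent nested-loop tally.

## Wobble-decoding classification

Every codon is classified by amino acid, wobble nucleotide, and the
anticodon nucleotide-34 route. For NNU/NNC codons: I34 when the sibling
NNA codon codes the same amino acid (inosine pairs with U, C and A), G34
otherwise; glycine is kept G34 as the known eukaryote exception despite
GGA coding Gly. CGA is the single NNA codon decoded exclusively by an I34
anticodon and carries a dedicated flag. A prokaryote mode remaps I34 to
G34 (inosine 34 being a eukaryote innovation). Stop codons have no
nt-34 class. The exact tRNA complement varies across organisms; this
table is a rule-derived default, not a per-species inventory.

## Density pipeline

1. **Offsets.** Each read's A-site nucleotide is `pos5 + offset(length)`.
   The default offset is 15 nt for every analyzed length in both classes
   (the canonical yeast value); calibration (`offsets="auto"`) chooses,
   per read length, the offset in [10, 20] maximizing an ORF-anchored
   score: counts whose shifted A-site lands in-ORF on frame 0 are
   rewarded and counts pushed outside the ORF are penalized. A pure
   periodicity score is degenerate modulo 3 on profiles without
   initiation pile-ups; the ORF-boundary penalty breaks that degeneracy,
   which matters because the synthetic generator deliberately does not
   simulate initiation/termination pile-ups. Lengths with under 50
   in-frame counts, or tied scores, fall back to the default with a
   warning.
2. **Frame.** The major periodicity frame is chosen dataset-wide (not per
   gene) as the frame carrying the most shifted counts; per-gene frames
   would be unstable for low-coverage genes.
3. **Codon aggregation.** Codon `i`'s raw density sums shifted counts at
   the major-peak position `3i + m` and the two flanking minor-peak
   positions. Consecutive windows tile the ORF, so each interior
   nucleotide position contributes to exactly one codon and totals are
   conserved; window positions outside `[0, L)` are dropped (codon 0 uses
   only positions >= 0, the final codon only positions < L — no spill
   into UTRs). Minor peaks are aggregated on raw counts *before* per-gene
   normalization; since normalization divides the whole gene by one
   constant, this order is equivalent to normalizing first up to that
   constant, and is simpler to test. A no-op deblurring hook is the
   contract point where externally deblurred tables can be substituted.
4. **Filters.** Genes are retained when ORF length is strictly greater
   than 198 nt and the raw class footprint total per nucleotide is
   strictly greater than 0.1 (1 footprint per 10 nt), computed per RFP
   class before offsetting.
5. **Normalization.** Each retained gene's vector is divided by its own
   mean, so the per-gene mean is 1 and codon instances are comparable
   across genes with equal weight. (The alternative reading — averaging
   per-gene means across genes — is available via the per-gene tallies
   the bootstrap already computes, but equal instance weighting is the
   default and the tested path.)
6. **Context comparison.** One row per sense A-site codon with a +1 codon
   inside the same ORF; `gnn_flag` is true when the +1 codon starts with
   G. Stop codons never appear as A-site rows; rows whose +1 codon is the
   stop are flagged and retained in the without-GNN group by default. The
   first and last codon of each ORF are excluded by default
   (`exclude_edge = 1`): start/stop pile-ups in real data are
   initiation/termination artifacts, not dwell signal. Per codon type the
   pooled with-GNN and without-GNN means, their ratio and the percent
   elevation `100*(ratio - 1)` are reported. No multiple-testing
   correction is applied across codon types; consumers read per-type
   two-tailed p-values at 0.01.

## Gene bootstrap

The resampling unit is the gene: each replicate draws `n_genes` genes
with replacement and recomputes the pooled statistic from per-gene
tallies with multiplicity honored. P-values use the add-one estimator
`p = 2 min[(1+#{b>=obs})/(n+1), (1+#{b<=obs})/(n+1)]`, capped at 1, so
p is never 0 and is safe at small `n_boot`.

Two procedures are provided for the context and G1-weight tests:

* **percentile** (default): the *difference* statistic (with-minus-without
  mean, or conditional-minus-unconditional G1 weight) is recomputed per
  gene resample and 0 is located two-tailed in that distribution. This is
  the standard percentile bootstrap of the estimator and is calibrated:
  the test suite verifies p-uniformity under null simulations (KS,
  alpha = 0.001) and the nominal 0.01 type-I error within binomial
  Monte-Carlo bands.
* **null-band**: the observed conditional statistic is located in the
  bootstrap distribution of the *unconditional* (or without-GNN)
  statistic — a reference-band procedure used in the ribosome-profiling
  literature. Under an iid null this is anti-conservative, for two
  reasons: the conditional tally is roughly a quarter the size of the
  reference tally, so its sampling variance is larger than the band
  width; and per-gene normalization anti-correlates the two group means
  within a gene. It is kept available (`method="null-band"`) for
  comparability, but the calibrated percentile method is the default and
  the one used by all shipped analyses.

Degenerate inputs (a single gene, or fewer than two genes contributing
both context groups) return p = 1 with an explicit flag rather than an
error, mirroring how sparse codon types must be handled in real data.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed once:

| parameter | default | meaning |
|---|---|---|
| ORF length | uniform 300-600 codons | mean ~450 codons, typical yeast scale |
| codon usage | uniform over 61 sense codons | composition null |
| adjacency_bias | 1.0 (preset "adjacency": 1.3) | odds multiplier for G-starting codons after NNU |
| dwell preset "paper_effect" | 1.4 on (A-site NNU, +1 GNN) | the documented headline elevation (~40%) |
| frame_weights | 0.70 / 0.15 / 0.15 | major and minor periodicity peaks |
| depth | lognormal, median 1 read/nt, sigma 0.5 | per-gene depth variation |
| 28-nt length mixture | 27:0.15, 28:0.55, 29:0.20, 30:0.10 | read-length composition |
| 21-nt length mixture | 20:0.2, 21:0.6, 22:0.2 | |
| true offsets | every length 15 | generator ground truth for calibration tests |
| noise | Poisson (optional gamma overdispersion) | simplest model consistent with the pipeline |

ORFs are drawn codon by codon (AUG start, stop-free body, one stop);
after an NNU codon the probability of each G-starting codon is multiplied
by `adjacency_bias` and renormalized. Counts are Poisson with expectation
`depth_g * 3 * dwell(g,i) * frame_weight_f / mean_dwell_g`, thinned over
the length mixture, and placed at
`5' = (3i + major_frame + delta_f) - offset(length)`. Every generated
footprint's A-site lies inside the ORF; 5' ends may be negative
(footprints spanning into the 5' UTR), which is what makes ORF-start
geometry informative for offset calibration. Minor-peak positions falling
outside `[0, L)` are dropped.

The closed-form expectation of the normalized density of a codon class is
its dwell multiplier divided by the gene's mean multiplier, which the
recovery tests assert within Monte-Carlo error. What the generator does
*not* emulate: realistic codon usage (supplyable as an input table),
initiation/termination pile-ups, UTR-positioned ribosomes, alignment and
mapping artifacts, and library-preparation sequence bias. Passing
recovery and calibration tests therefore demonstrates correctness of the
estimator under the stated model, not robustness to those real-data
features.

## Problem sizes

The shipped analyses use sizes chosen to make replicate studies routine:
effect recovery at 200 genes (~450 codons, ~1 read/nt, n_boot = 1000),
calibration studies at 100-300 replicate simulations of 40-100 genes with
n_boot 300-1000. Bootstraps are vectorized over per-gene tallies
(multinomial multiplicity matrices times per-gene sufficient statistics),
so n_boot = 10000 on thousands of genes remains cheap.

## Known limitations

* The decoding table is rule-derived; organisms with unusual tRNA
  complements need a custom table.
* Offset calibration relies on ORF-boundary geometry; datasets whose
  reads were pre-trimmed to ORF interiors fall back to the default table.
* The 198-nt length filter and the 0.1/nt density filter are strict
  inequalities by contract; boundary genes are excluded.
* Deblurring of high-expression profiles is out of scope; the pipeline
  consumes already-positioned 5'-end counts and provides a substitution
  point for externally deblurred tables.
* Expression stratification uses the ceiling convention for the stratum
  size with lexicographic tie-breaks; counts may differ by one gene from
  conventions that round differently.
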