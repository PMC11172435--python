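# ribocontext

Codon-adjacency statistics and A-site ribosome-density context analysis
for ribosome profiling (Ribo-seq) data.

## The scientific problem

During translation the ribosome decodes the A-site codon while the next
(+1) codon sits against the decoding-center surface that extends the
A-site tRNA anticodon. Two empirical signatures follow if the identity of
the +1 codon modulates elongation:

1. **Sequence composition.** In coding sequences, G is enriched at codon
   position 1, and this G1 enrichment is stronger for codons that are
   3'-adjacent to NNU codons (codons with wobble U). ribocontext
   quantifies this with position weight matrices
   `weight(pos, N) = log2(f_obs(pos, N) / f_exp(N))`, where `f_exp` is the
   background nucleotide frequency of the same ORF set pooled over all
   positions, and conditional PWMs restricted to codons following a
   reference class.
2. **Ribosome dwell.** In footprint data, codons decoded slowly
   accumulate footprints. Assigning each footprint's A-site by a fixed 5'
   offset, summing the major 3-nt-periodicity peak with its two flanking
   minor peaks into per-codon densities, and normalizing within each gene
   (gene mean = 1) gives a dwell proxy. ribocontext compares, per A-site
   codon type, the mean normalized density of instances followed by +1
   GNN versus not followed by +1 GNN, separately for 27-30 nt footprints
   ("28-nt RFPs", translocating ribosomes) and 20-22 nt footprints
   ("21-nt RFPs", pre-accommodation ribosomes).

Inference in both analyses is a **gene-level bootstrap**: genes are
resampled with replacement, the pooled statistic is recomputed per
resample, and a two-tailed p-value is obtained with a small-sample-safe
add-one estimator. Codons are additionally classified by their anticodon
nucleotide-34 decoding route (G34 vs inosine I34, with CGA the single
I34-exclusive NNA codon), which groups NNU codon types in the summaries.

Because published footprint datasets require an external accession, the
package ships a first-class synthetic-data module that generates ORF sets
and footprint tables with known injected effects (adjacency bias, dwell
multipliers, depth variation, frame structure), so every pipeline
statistic can be checked against ground truth.

## Worked example

```python
import ribocontext as rc

# synthetic study: 200 genes, ~450 codons, ~1 read/nt, with a 1.4x dwell
# multiplier injected on A-site NNU codons followed by +1 GNN
cfg = rc.preset("paper_effect", seed=1, n_genes=200)
orfs, truth = rc.gen_orfs(cfg)
counts, truth = rc.gen_profiles(orfs, cfg, truth)

res = rc.RiboDensityModel(counts, orfs, rfp_class="28nt").fit(n_boot=1000, seed=1)
print(res.summary())
```

prints

```
Ribosome density analysis [28nt]
============================================================
genes: 200 input, 200 pass length, 200 pass density
offsets: default {27: 15, 28: 15, 29: 15, 30: 15}
major frame: 0
codon types compared: 61 (61 testable, 17 with p < 0.01)
mean NNU percent elevation (+1 GNN): 39.7%
```

All 200 genes pass the length (> 198 nt) and density (> 1 footprint per
10 nt) filters; the major periodicity frame is recovered; 17 codon types
are significant at 0.01 (the 16 NNU types carrying the injected effect,
plus about the expected one false positive among the 45 null types); and
the mean percent elevation over NNU types, 39.7%, recovers the injected
40%. A single codon type:

```python
comp = res.comparison("GCU")
# mean_with=1.358  mean_without=0.984  ratio=1.381  elev=38.1%  p=0.001998
```

The composition side runs the same way:

```python
adj = rc.CodonAdjacencyModel(orfs).fit(n_boot=1000, seed=1)
print(adj.summary())
```

On this dwell-only simulation (no sequence adjacency bias) the
conditional-minus-unconditional G1 weight is near zero (0.018, bootstrap
p = 0.24), as it should be; simulating with `rc.preset("adjacency", ...)`
instead plants a 1.3x G-start odds bias after NNU codons, which the same
test detects at p < 0.01.

A command-line interface mirrors the library
(`ribocontext simulate | codon-stats | ribo-density | compare | report |
run-all`); `run-all` writes TSV tables, figures, the resolved
configuration and a SHA-256 manifest that is byte-stable for a fixed seed.

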