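"""Generator determinism, null behaviour and closed-form expectations."""

import numpy as np
import pytest

import ribocontext as rc
from ribocontext.codons import codon_mask
from ribocontext.io import read_footprint_table


def test_seed_mandatory_and_validation():
    with pytest.raises(TypeError):
        rc.SimConfig()  # seed is required
    with pytest.raises(ValueError, match="frame_weights"):
        rc.SimConfig(seed=1, frame_weights=(0.5, 0.3, 0.1))
    with pytest.raises(ValueError, match="infeasible"):
        rc.SimConfig(seed=1, min_codons=10, max_codons=5)
    with pytest.raises(ValueError, match="multiplier"):
        rc.DwellEffect(multiplier=0.0)


def test_orf_structure():
    cfg = rc.preset("null", seed=4, n_genes=20, min_codons=50, max_codons=80)
    orfs, truth = rc.gen_orfs(cfg)
    stops = {"UAA", "UAG", "UGA"}
    for gene in orfs:
        seq = orfs[gene]
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        assert codons[0] == "AUG"
        assert codons[-1] in stops
        assert not any(c in stops for c in codons[:-1])  # no internal stops
        assert 50 <= len(codons) <= 80


def test_same_seed_identical_fasta(tmp_path):
    cfg = rc.preset("paper_effect", seed=9, n_genes=10, min_codons=50, max_codons=80)
    for d in ("a", "b"):
        rc.write_dataset(tmp_path / d, cfg)
    assert (tmp_path / "a/orfs.fasta").read_bytes() == (tmp_path / "b/orfs.fasta").read_bytes()
    assert (tmp_path / "a/counts_28nt.tsv").read_bytes() == (
        tmp_path / "b/counts_28nt.tsv"
    ).read_bytes()
    assert (tmp_path / "a/expression.tsv").read_bytes() == (
        tmp_path / "b/expression.tsv"
    ).read_bytes()


def test_null_adjacency_frequencies_match():
    """With adjacency_bias = 1, the G1 frequency after NNU matches the
    unconditional G1 frequency (|delta| < 0.01 at ~1e5 codons)."""
    cfg = rc.preset("null", seed=15, n_genes=250, min_codons=400, max_codons=400)
    orfs, _ = rc.gen_orfs(cfg)
    nnu, gnn = codon_mask("NNU"), codon_mask("GNN")
    after, total_after, g_all, total = 0, 0, 0, 0
    for gene in orfs:
        c = orfs.codons(gene)
        g_all += gnn[c].sum()
        total += c.size
        follow = c[1:][nnu[c[:-1]]]
        after += gnn[follow].sum()
        total_after += follow.size
    assert abs(after / total_after - g_all / total) < 0.01


def test_biased_adjacency_frequencies_shift():
    cfg = rc.preset("adjacency", seed=15, n_genes=100, min_codons=300, max_codons=300)
    orfs, truth = rc.gen_orfs(cfg)
    assert truth.adjacency_pairs > 0
    cond = rc.adjacency_pwm(orfs, "NNU").weight(1, "G")
    uncond = rc.positional_weight_matrix(orfs).weight(1, "G")
    assert cond > uncond


def test_expected_reads_per_gene(null_dataset):
    """Total reads per gene ~ depth * length within 3 sd of the Poisson sum
    (minus the two boundary minor-peak cells that are dropped)."""
    _, orfs, counts, truth = null_dataset
    totals = counts.gene_totals()
    for gene in list(orfs)[:25]:
        expected = truth.expected_reads[gene]
        # dropped cells: upstream minor peak of codon 0, downstream of last
        edge = truth.depth[gene] * 3 * 0.15 * 2
        sd = np.sqrt(expected)
        assert abs(totals.get(gene, 0) - (expected - edge)) < 3 * sd + 1


def test_closed_form_normalized_density(effect_dataset):
    """Pipeline normalized density of the boosted class matches the
    truth's closed-form expectation within Monte-Carlo error."""
    _, orfs, counts, truth = effect_dataset
    res = rc.RiboDensityModel(counts, orfs).fit(n_boot=100, seed=1, codon_types=["GCU"])
    gene = res.filter_report.retained[0]
    expect = truth.expected_normalized_density(gene)
    got = res.density[gene]
    # per-codon Poisson noise: compare gene-level means over effect codons
    boosted = truth.dwell[gene] > 1.0
    n = boosted.sum()
    se = np.sqrt(np.var(got[boosted]) / n)
    assert got[boosted].mean() == pytest.approx(expect[boosted].mean(), abs=4 * se + 0.02)


def test_round_trip_through_files(tmp_path):
    """Generated datasets are consumable by the standard readers."""
    cfg = rc.preset("paper_effect", seed=31, n_genes=15, min_codons=80, max_codons=120)
    paths = rc.write_dataset(tmp_path, cfg, rfp_classes=("28nt", "21nt"))
    orfs = rc.read_orf_fasta(paths["orfs"])
    assert len(orfs) == 15
    fc28 = read_footprint_table(paths["counts_28nt"])
    fc21 = read_footprint_table(paths["counts_21nt"])
    assert set(fc28.df["read_length"]) <= {27, 28, 29, 30}
    assert set(fc21.df["read_length"]) <= {20, 21, 22}
    expr = rc.read_expression_table(paths["expression"])
    assert set(expr) == set(orfs.gene_ids)
    assert paths["truth"].exists()


def test_gen_expression_determinism_and_sigma_zero():
    cfg = rc.preset("null", seed=8, n_genes=12, min_codons=50, max_codons=60)
    orfs, _ = rc.gen_orfs(cfg)
    a = rc.gen_expression(orfs, cfg)
    b = rc.gen_expression(orfs, cfg)
    assert a == b and len(a) == 12
    import dataclasses

    flat = rc.gen_expression(orfs, dataclasses.replace(cfg, expression_sigma=0.0))
    assert len(set(flat.values())) == 1


def test_unknown_preset():
    with pytest.raises(ValueError, match="unknown preset"):
        rc.preset("bogus", seed=1)
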