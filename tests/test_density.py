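"""Offset calibration, density aggregation, filtering, normalization."""

import numpy as np
import pandas as pd
import pytest

import ribocontext as rc
from ribocontext.density import OffsetTable, read_offset_table, write_offset_table
from ribocontext.io import FootprintCounts


def _counts(rows):
    return FootprintCounts(
        pd.DataFrame(rows, columns=["gene_id", "pos5", "read_length", "count"])
    )


class TestOffsets:
    def test_default_table(self):
        tab = OffsetTable.default("28nt")
        assert tab.offsets == {27: 15, 28: 15, 29: 15, 30: 15}
        tab21 = OffsetTable.default("21nt")
        assert set(tab21.offsets) == {20, 21, 22}

    def test_range_validation(self):
        with pytest.raises(ValueError, match="outside"):
            OffsetTable({28: 25}, "28nt")

    @pytest.mark.parametrize("true_offset", [14, 15])
    def test_recovers_generator_truth(self, true_offset):
        cfg = rc.preset(
            "null", seed=42, n_genes=60, depth_median=0.5,
            true_offsets={l: true_offset for l in (27, 28, 29, 30)},
        )
        orfs, _ = rc.gen_orfs(cfg)
        counts, _ = rc.gen_profiles(orfs, cfg)
        tab = rc.calibrate_offsets(counts, orfs, "28nt")
        assert tab.offsets == {l: true_offset for l in (27, 28, 29, 30)}
        assert tab.source == "calibrated" and not tab.warnings

    def test_insufficient_signal_falls_back(self):
        counts = _counts([("g", 0, 28, 1)])
        orfs = rc.OrfSet({"g": "AUG" + "GCU" * 80 + "UAA"})
        tab = rc.calibrate_offsets(counts, orfs, "28nt")
        assert tab.offsets[28] == 15 and tab.warnings

    def test_empty_counts_is_an_error(self, tiny_orfs):
        with pytest.raises(ValueError, match="no footprints"):
            rc.calibrate_offsets(_counts([("zz", 0, 28, 1)]), tiny_orfs, "28nt")

    def test_table_round_trip(self, tmp_path):
        tab = OffsetTable({27: 14, 28: 15}, "28nt")
        write_offset_table(tab, tmp_path / "o.tsv")
        back = read_offset_table(tmp_path / "o.tsv", "28nt")
        assert back.offsets == tab.offsets


class TestCodonDensities:
    def test_major_and_minor_peaks_sum(self):
        """Shifted per-nt counts (2, 10, 3) around codon 1 give density 15."""
        orfs = rc.OrfSet({"g": "AUGGCUGAAUAA"})
        # offset 15: A-site positions 2, 3, 4 = codon-1 window for frame 0
        counts = _counts([("g", -13, 28, 2), ("g", -12, 28, 10), ("g", -11, 28, 3)])
        raw, major = rc.codon_densities(counts, orfs, OffsetTable.default("28nt"), "28nt")
        assert major == 0
        assert raw["g"].tolist() == [0.0, 15.0, 0.0, 0.0]

    def test_zero_count_gene_gives_zero_vector(self, tiny_orfs):
        counts = _counts([("g1", 0, 28, 1)])
        raw, _ = rc.codon_densities(counts, tiny_orfs, OffsetTable.default("28nt"), "28nt")
        assert raw["g2"].sum() == 0.0 and raw["g2"].size == tiny_orfs.n_codons("g2")

    def test_count_conservation(self, null_dataset):
        """Interior shifted counts are fully partitioned into codon sums."""
        _, orfs, counts, _ = null_dataset
        raw, major = rc.codon_densities(counts, orfs, OffsetTable.default("28nt"), "28nt")
        df = counts.for_class("28nt")
        pos = df["pos5"].to_numpy() + 15
        L = np.array([orfs.length_nt(g) for g in df["gene_id"]])
        K = L // 3
        ci = (pos - major + 1) // 3
        interior = (pos >= 0) & (pos < L) & (ci >= 0) & (ci < K)
        assert sum(v.sum() for v in raw.values()) == pytest.approx(
            df["count"].to_numpy()[interior].sum()
        )

    def test_missing_read_length_raises(self):
        orfs = rc.OrfSet({"g": "AUG" + "GCU" * 80 + "UAA"})
        counts = _counts([("g", 0, 29, 1)])
        with pytest.raises(ValueError, match="missing from offset table"):
            rc.codon_densities(counts, orfs, OffsetTable({28: 15}, "28nt"), "28nt")


class TestFilterGenes:
    def _orfs(self):
        return rc.OrfSet(
            {
                "len198": "AUG" + "GCU" * 64 + "UAA",      # exactly 198 nt
                "len300": "AUG" + "GCU" * 98 + "UAA",      # 300 nt
                "len201": "AUG" + "GCU" * 65 + "UAA",      # 201 nt
            }
        )

    def test_strict_thresholds(self):
        orfs = self._orfs()
        counts = _counts(
            [("len198", 0, 28, 1000), ("len300", 0, 28, 30), ("len201", 0, 28, 41)]
        )
        report, retained = rc.filter_genes(counts, orfs, "28nt")
        # 198 nt is not > 198; 30/300 = exactly 0.1/nt is not above threshold
        assert retained == ["len201"]
        assert report.n_input == 3
        assert report.n_pass_length == 2
        assert report.n_pass_density == 1
        assert "length" in report.reasons["len198"]
        assert "density" in report.reasons["len300"]

    def test_density_uses_raw_class_totals(self):
        orfs = self._orfs()
        # 21nt reads must not count toward the 28nt-class density
        counts = _counts([("len201", 0, 21, 1000), ("len201", 0, 28, 1)])
        _, retained = rc.filter_genes(counts, orfs, "28nt")
        assert retained == []
        _, retained21 = rc.filter_genes(counts, orfs, "21nt")
        assert retained21 == ["len201"]


def test_deblur_hook_is_applied_before_processing(null_dataset):
    """The deblur hook transforms the counts table ahead of the pipeline;
    the default is the identity."""
    _, orfs, counts, _ = null_dataset
    seen = {}

    def fake_deblur(fc):
        seen["n"] = len(fc)
        return fc

    model = rc.RiboDensityModel(counts, orfs, deblur=fake_deblur)
    assert seen["n"] == len(counts)
    assert model.counts is counts


class TestNormalize:
    def test_examples(self):
        raw = {"a": np.array([2.0, 4.0, 6.0]), "b": np.array([5.0, 5.0]),
               "c": np.array([0.0, 3.0, 3.0])}
        mat = rc.normalize_densities(raw, "28nt")
        assert mat["a"].tolist() == [0.5, 1.0, 1.5]
        assert mat["b"].tolist() == [1.0, 1.0]
        assert mat["c"].tolist() == [0.0, 1.5, 1.5]

    def test_per_gene_mean_is_one(self, effect_dataset):
        _, orfs, counts, _ = effect_dataset
        raw, major = rc.codon_densities(counts, orfs, OffsetTable.default("28nt"), "28nt")
        mat = rc.normalize_densities(raw, "28nt", major)
        for gene in list(mat)[:20]:
            assert mat[gene].mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_gene_is_an_error(self):
        with pytest.raises(ValueError, match="zero footprint density"):
            rc.normalize_densities({"g": np.zeros(4)}, "28nt")
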