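"""Context annotation, the +1 GNN comparison and the RFP-class summary."""

import dataclasses

import numpy as np
import pytest

import ribocontext as rc
from ribocontext.context import ContextComparison, comparisons_frame
from ribocontext.density import CodonDensityMatrix


def _matrix(records, values):
    return CodonDensityMatrix(
        "28nt",
        {g: np.asarray(v, dtype=float) for g, v in values.items()},
        {g: float(np.sum(v)) for g, v in values.items()},
        0,
    )


class TestAnnotate:
    def test_definition_example(self):
        """[AUG, GCU, GAA, UAA]: three A-site rows; AUG's and GCU's +1
        codons start with G; GAA's +1 codon is the stop (flagged, kept in
        the without-GNN group)."""
        orfs = rc.OrfSet({"g": "AUGGCUGAAUAA"})
        mat = _matrix(orfs, {"g": [1.0, 2.0, 3.0, 0.0]})
        rows = rc.annotate_contexts(mat, orfs, exclude_edge=0)
        assert len(rows) == 3
        assert rows["asite_codon"].tolist() == ["AUG", "GCU", "GAA"]
        assert rows["gnn_flag"].tolist() == [True, True, False]
        assert rows["stop_next"].tolist() == [False, False, True]
        assert rows["density"].tolist() == [1.0, 2.0, 3.0]

    def test_two_sense_codons(self):
        orfs = rc.OrfSet({"g": "AUGGCUUAA"})
        mat = _matrix(orfs, {"g": [1.0, 1.0, 1.0]})
        assert len(rc.annotate_contexts(mat, orfs, exclude_edge=0)) == 2

    def test_edge_exclusion_default(self):
        orfs = rc.OrfSet({"g": "AUGGCUGAAUAA"})
        mat = _matrix(orfs, {"g": [1.0, 2.0, 3.0, 0.0]})
        rows = rc.annotate_contexts(mat, orfs)  # exclude_edge=1
        assert rows["asite_codon"].tolist() == ["GCU", "GAA"]

    def test_drop_stop_next_option(self):
        orfs = rc.OrfSet({"g": "AUGGCUGAAUAA"})
        mat = _matrix(orfs, {"g": [1.0, 2.0, 3.0, 0.0]})
        rows = rc.annotate_contexts(mat, orfs, exclude_edge=0, keep_stop_next=False)
        assert rows["asite_codon"].tolist() == ["AUG", "GCU"]

    def test_gnn_flags_match_planted_adjacency(self, null_dataset):
        """Total NNU->+1 GNN flags equal the generator's planted pair count."""
        _, orfs, _, truth = null_dataset
        mat = _matrix(orfs, {g: np.ones(orfs.n_codons(g)) for g in orfs})
        rows = rc.annotate_contexts(mat, orfs, exclude_edge=0)
        nnu_gnn = ((rows["asite_codon"].str.endswith("U")) & rows["gnn_flag"]).sum()
        assert nnu_gnn == truth.adjacency_pairs

    def test_length_mismatch_raises(self):
        orfs = rc.OrfSet({"g": "AUGGCUGAAUAA"})
        mat = _matrix(orfs, {"g": [1.0, 2.0]})
        with pytest.raises(ValueError, match="length mismatch"):
            rc.annotate_contexts(mat, orfs)


class TestContextComparison:
    def test_recovers_injected_dwell_multiplier(self, effect_dataset):
        """Injected 1.4x dwell on NNU/+1 GNN shows up as mean ratio ~ 1.4
        over the 16 NNU codon types, with nearly all individually
        significant."""
        _, orfs, counts, _ = effect_dataset
        nnu_types = [c + "U" for c in
                     ("AA", "AC", "AG", "AU", "CA", "CC", "CG", "CU",
                      "GA", "GC", "GG", "GU", "UA", "UC", "UG", "UU")]
        res = rc.RiboDensityModel(counts, orfs).fit(
            n_boot=1000, seed=5, codon_types=nnu_types
        )
        ratios = [c.ratio for c in res.comparisons]
        assert np.mean(ratios) == pytest.approx(1.4, abs=0.1)
        assert sum(c.p_two_tailed < 0.01 for c in res.comparisons) >= 13

    def test_null_types_are_not_elevated(self, effect_dataset):
        _, orfs, counts, _ = effect_dataset
        res = rc.RiboDensityModel(counts, orfs).fit(
            n_boot=1000, seed=5, codon_types=["GCA", "AAG"]
        )
        for comp in res.comparisons:
            assert comp.ratio == pytest.approx(1.0, abs=0.1)

    def test_seeded_determinism(self, null_dataset):
        _, orfs, counts, _ = null_dataset
        fits = [
            rc.RiboDensityModel(counts, orfs).fit(n_boot=300, seed=9, codon_types=["GCU"])
            for _ in range(2)
        ]
        assert (
            fits[0].comparisons[0].p_two_tailed == fits[1].comparisons[0].p_two_tailed
        )

    def test_type_subset_independence(self, null_dataset):
        """A type's result does not depend on which other types are fitted."""
        _, orfs, counts, _ = null_dataset
        model = rc.RiboDensityModel(counts, orfs)
        alone = model.fit(n_boot=300, seed=9, codon_types=["GCU"]).comparisons[0]
        paired = model.fit(n_boot=300, seed=9, codon_types=["AAA", "GCU"]).comparison("GCU")
        assert alone.p_two_tailed == paired.p_two_tailed

    def test_single_gene_is_degenerate(self):
        orfs = rc.OrfSet({"g": "AUG" + "GCUGAA" * 20 + "UAA"})
        mat = _matrix(orfs, {"g": np.ones(orfs.n_codons("g"))})
        rows = rc.annotate_contexts(mat, orfs)
        comp = rc.context_comparison(rows, "GCU", "28nt", n_boot=100, seed=1)
        assert comp.p_two_tailed == 1.0
        assert comp.flag == "insufficient instances"

    def test_no_instances(self):
        orfs = rc.OrfSet({"g": "AUGGCUGAAUAA", "h": "AUGGCUGAAUAA"})
        mat = _matrix(orfs, {g: np.ones(4) for g in ("g", "h")})
        rows = rc.annotate_contexts(mat, orfs)
        comp = rc.context_comparison(rows, "CGG", "28nt", n_boot=100, seed=1)
        assert comp.flag == "no instances" and comp.p_two_tailed == 1.0


class TestClassSummary:
    def _comp(self, codon, cls, elev, p=0.5):
        return ContextComparison(codon, cls, 10, 30, 1.0 + elev / 100, 1.0,
                                 1.0 + elev / 100, elev, p, 100, None, 10)

    def test_identical_distributions_give_p_one(self):
        comps21 = [self._comp(c, "21nt", e) for c, e in
                   [("GCU", 10.0), ("ACU", 20.0), ("GCC", 5.0), ("AUC", 7.0)]]
        comps28 = [self._comp(c, "28nt", e) for c, e in
                   [("GCU", 10.0), ("ACU", 20.0), ("GCC", 5.0), ("AUC", 7.0)]]
        df = rc.class_summary(comps21, comps28)
        assert df["t_p_two_tailed"].tolist() == pytest.approx([1.0] * len(df))

    def test_single_type_group_raises(self):
        comps21 = [self._comp("GCU", "21nt", 10.0), self._comp("ACU", "21nt", 12.0),
                   self._comp("AAA", "21nt", 1.0)]
        comps28 = [self._comp("GCU", "28nt", 10.0), self._comp("ACU", "28nt", 12.0),
                   self._comp("AAA", "28nt", 1.0)]
        with pytest.raises(ValueError, match="fewer than 2 codon types"):
            rc.class_summary(comps21, comps28)

    def test_class_specific_effects_detected(self):
        """21-nt elevation on all classes but 28-nt elevation on NNU only:
        the NNC and NNA groups differ significantly between classes."""
        base = rc.preset("null", seed=55, n_genes=100, min_codons=200, max_codons=400)
        effects21 = (rc.DwellEffect("NNN", "GNN", 1.4, rfp_class="21nt"),)
        effects28 = (rc.DwellEffect("NNU", "GNN", 1.4, rfp_class="28nt"),)
        cfg = dataclasses.replace(base, dwell_effects=effects21 + effects28)
        orfs, _ = rc.gen_orfs(cfg)
        results = {}
        for cls in ("21nt", "28nt"):
            ccfg = dataclasses.replace(cfg, rfp_class=cls)
            counts, _ = rc.gen_profiles(orfs, ccfg)
            results[cls] = rc.RiboDensityModel(counts, orfs, rfp_class=cls).fit(
                n_boot=200, seed=3
            )
        df = rc.compare_rfp_classes(results["21nt"], results["28nt"])
        by_group = df.set_index("group")
        for group in ("NNC", "NNA"):
            assert by_group.loc[group, "t_p_two_tailed"] < 0.01
            assert by_group.loc[group, "mean_elev_21nt"] > 20
            assert abs(by_group.loc[group, "mean_elev_28nt"]) < 10
        # NNU elevated in both classes
        assert by_group.loc["NNU(G34)", "mean_elev_28nt"] > 20


def test_comparisons_frame_column_order():
    frame = comparisons_frame([])
    assert list(frame.columns)[:3] == ["asite_codon_type", "two_nt_label", "rfp_class"]
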