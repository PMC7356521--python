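"""Cross-line set algebra: Criteria I-III, fold changes, Venn accounting."""

import math

import pandas as pd
import pytest

import endosurf as es
from endosurf.endocytosis_classifier import EndocytosisCallResult
from endosurf.surface_classifier import SurfaceCallResult


def surface_result(cell_line, surface_ids, other_ids=()):
    ratios = {p: 100.0 for p in surface_ids} | {p: 1.5 for p in other_ids}
    return SurfaceCallResult.from_ratios(cell_line, threshold=8.0, ratios=ratios)


def endo_result(cell_line, universe, endocytic_ids, b_ids=()):
    return EndocytosisCallResult.from_sets(cell_line, universe, endocytic_ids, b_ids)


def means_with_internal(values: dict[str, float]) -> pd.DataFrame:
    df = pd.DataFrame({"mean_internalization": pd.Series(values, dtype=float)})
    df["mean_surface"] = df["mean_internalization"]
    df.index.name = "protein_id"
    return df


class TestFoldChange:
    @pytest.mark.parametrize(
        "a, b, expected", [(400.0, 100.0, 4.0), (500.0, 100.0, 5.0), (10.0, 0.0, math.inf)]
    )
    def test_values(self, a, b, expected):
        assert es.fold_change(a, b) == expected

    def test_both_zero_undefined(self):
        assert math.isnan(es.fold_change(0.0, 0.0))

    def test_recovers_planted_line_multipliers_noise_free(self, noisefree_sim, noisefree_pipeline):
        truth = noisefree_sim.truth_frame()
        sel = noisefree_pipeline.selectivity.table
        shared = truth[(truth["mult_target"] > 0) & (truth["mult_comparator"] > 0)]
        checked = 0
        for pid, row in shared.iterrows():
            f = sel["fold_change"].get(pid, math.nan)
            if math.isnan(f):
                continue
            expected = (row["mult_target"] * row["internal_ratio"]) / (
                row["mult_comparator"] * row["internal_ratio_comparator"]
            )
            assert f == pytest.approx(expected, rel=1e-9)
            checked += 1
        assert checked > 10

    def test_boundary_fold_not_selected(self):
        universe = ["p1"]
        surf_a = surface_result("A", universe)
        surf_b = surface_result("B", universe)
        endo_a = endo_result("A", universe, {"p1"})
        endo_b = endo_result("B", universe, {"p1"})
        ref = es.ReferenceList(name="ref", members={"p1"})
        report = es.select_candidates(
            surf_a, endo_a, surf_b, endo_b, ref,
            means_a=means_with_internal({"p1": 400.0}),
            means_b=means_with_internal({"p1": 100.0}),
        )
        assert report.venn["criterion_III"] == 0  # strict > 4 at the threshold
        assert report.final_candidates == set()


class TestSelectCandidates:
    def test_hand_enumerated_three_protein_example(self):
        universe = ["p1", "p2", "p3"]
        surf_a = surface_result("A", ["p1", "p2", "p3"])
        surf_b = surface_result("B", ["p2", "p3"], other_ids=["p1"])
        endo_a = endo_result("A", universe, {"p1", "p2"})
        endo_b = endo_result("B", universe, {"p2"})
        ref = es.ReferenceList(name="ref", members={"p1", "p2"})
        report = es.select_candidates(
            surf_a, endo_a, surf_b, endo_b, ref,
            means_a=means_with_internal({"p2": 500.0}),
            means_b=means_with_internal({"p2": 100.0}),
        )
        tab = report.table
        assert tab.loc["p1", "criterion_selected"] == "I"
        assert tab.loc["p2", "criterion_selected"] == "III"
        assert report.venn["criterion_II"] == 0
        assert report.final_candidates == {"p1", "p2"}

    def test_identical_lines_yield_nothing(self):
        universe = ["p1", "p2"]
        surf = surface_result("A", universe)
        endo = endo_result("A", universe, {"p1", "p2"})
        ref = es.ReferenceList(name="ref", members=set(universe))
        means = means_with_internal({"p1": 100.0, "p2": 50.0})
        report = es.select_candidates(
            surf, endo, surface_result("B", universe), endo_result("B", universe, {"p1", "p2"}),
            ref, means_a=means, means_b=means,
        )
        assert report.venn["criterion_I"] == 0
        assert report.venn["criterion_II"] == 0
        assert report.venn["criterion_III"] == 0  # all fold changes are 1
        assert report.venn["mean_fold_change_arithmetic"] == pytest.approx(1.0)

    def test_endocytic_outside_surface_is_contract_breach(self):
        universe = ["p1"]
        surf_a = surface_result("A", [], other_ids=universe)  # p1 not cell_surface
        endo_a = endo_result("A", universe, {"p1"})
        with pytest.raises(ValueError, match="contract"):
            es.select_candidates(
                surf_a, endo_a, surface_result("B", universe), endo_result("B", universe, set()),
                es.ReferenceList(name="ref", members={"p1"}),
            )

    def test_empty_reference_rejected(self):
        universe = ["p1"]
        with pytest.raises(ValueError, match="reference"):
            es.select_candidates(
                surface_result("A", universe), endo_result("A", universe, set()),
                surface_result("B", universe), endo_result("B", universe, set()),
                es.ReferenceList(name="ref", members=set()),
            )


class TestVennAccounting:
    def test_conservation_identity(self, default_pipeline):
        """|selective endocytic| = |criterion I pre-reference| + |criterion II pre-reference|."""
        venn = default_pipeline.selectivity.venn
        assert (
            venn["selective_endocytic"]
            == venn["criterion_I_pre_reference"] + venn["criterion_II_pre_reference"]
        )

    def test_counts_match_brute_force_recount_of_flags(self, default_pipeline):
        tab = default_pipeline.selectivity.table
        venn = default_pipeline.selectivity.venn
        surf_a = set(tab.index[tab["surface_in_A"]])
        surf_b = set(tab.index[tab["surface_in_B"]])
        endo_a = set(tab.index[tab["endocytic_in_A"]])
        endo_b = set(tab.index[tab["endocytic_in_B"]])
        ref = set(tab.index[tab["in_reference"]])
        assert venn["selective_surface"] == len(surf_a - surf_b)
        assert venn["common_surface"] == len(surf_a & surf_b)
        assert venn["selective_endocytic"] == len(endo_a - endo_b)
        assert venn["common_endocytic"] == len(endo_a & endo_b)
        assert venn["criterion_I_pre_reference"] == len((endo_a - endo_b) & (surf_a - surf_b))
        assert venn["criterion_II_pre_reference"] == len((endo_a - endo_b) & (surf_a & surf_b))
        crit3 = {
            p for p in endo_a & endo_b
            if not math.isnan(tab.loc[p, "fold_change"]) and tab.loc[p, "fold_change"] > 4.0
        }
        assert venn["criterion_III_pre_reference"] == len(crit3)
        assert venn["criterion_I"] == len((endo_a - endo_b) & (surf_a - surf_b) & ref)
        assert venn["final_candidates"] == len(default_pipeline.selectivity.final_candidates)

    def test_swapping_lines_inverts_selectivity(self, default_pipeline, default_sim):
        """With lines swapped, criterion III membership uses the reciprocal fold."""
        p = default_pipeline
        swapped = es.select_candidates(
            p.comparator.surface, p.comparator.endocytosis,
            p.target.surface, p.target.endocytosis,
            default_sim.reference,
            means_a=p.comparator.means, means_b=p.target.means,
        )
        assert swapped.venn["selective_surface"] == (
            p.selectivity.venn["surface_B"] - p.selectivity.venn["common_surface"]
        )
        tab, stab = p.selectivity.table, swapped.table
        common = stab.index[stab["endocytic_in_A"] & stab["endocytic_in_B"]]
        for pid in common:
            f, g = tab.loc[pid, "fold_change"], stab.loc[pid, "fold_change"]
            if math.isfinite(f) and f > 0:
                assert g == pytest.approx(1.0 / f, rel=1e-9)
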