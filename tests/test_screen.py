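import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import orscreen as ors
from orscreen.screen import ScreenError, ZScoreMatrix

from conftest import make_expr, screen_bundle


def _expr_from(ref_rows: dict, tumor_rows: dict | None = None):
    """Build a log2-stage ExpressionMatrix from per-gene reference/tumor rows."""
    genes = list(ref_rows)
    n_ref = len(next(iter(ref_rows.values())))
    tumor_rows = tumor_rows or {g: [] for g in genes}
    n_tum = len(next(iter(tumor_rows.values())))
    cols = [f"T{i}" for i in range(n_tum)] + [f"N{i}" for i in range(n_ref)]
    data = {g: list(tumor_rows[g]) + list(ref_rows[g]) for g in genes}
    values = pd.DataFrame(data, index=cols).T
    roles = pd.Series(["tumor"] * n_tum + ["reference"] * n_ref, index=cols)
    return make_expr(values, roles)


class TestReferenceStats:
    def test_constant_reference_unscreenable(self):
        expr = _expr_from({"G1": [3, 3, 3, 3]}, {"G1": [5.0]})
        ref = ors.reference_stats(expr)
        assert ref.mean["G1"] == 3
        assert ref.sd["G1"] == 0
        assert ref.unscreenable_genes == ["G1"]

    def test_hand_computed_sd(self):
        # sample SD of (1,2,3,4) with n-1 denominator
        expr = _expr_from({"G1": [1, 2, 3, 4]}, {"G1": [5.0]})
        ref = ors.reference_stats(expr)
        assert ref.mean["G1"] == pytest.approx(2.5)
        assert ref.sd["G1"] == pytest.approx(1.29099, abs=1e-4)
        assert ref.screenable["G1"]

    def test_single_reference_sample_rejected(self):
        expr = _expr_from({"G1": [3]}, {"G1": [5.0]})
        with pytest.raises(ScreenError, match="reference samples"):
            ors.reference_stats(expr)


class TestZScores:
    @pytest.mark.parametrize(
        "x,ref_vals,expected",
        [
            (3.0, [2, 4], 0.0),      # mean 3, equal to reference mean
            (5.0, [2, 4], 1.41421),  # (5-3)/sqrt(2)
        ],
    )
    def test_values(self, x, ref_vals, expected):
        expr = _expr_from({"G1": ref_vals}, {"G1": [x]})
        ref = ors.reference_stats(expr)
        z = ors.zscores(expr, ref)
        assert z.values.loc["G1", "T0"] == pytest.approx(expected, abs=1e-4)

    def test_hand_example_with_given_mean_sd(self):
        # X=2, mean=3, sd=0.5 -> Z=-2; construct a reference with those stats
        expr = _expr_from({"G1": [2.5, 3.5]}, {"G1": [2.0, 5.0, 3.0]})
        ref = ors.reference_stats(expr)
        assert ref.mean["G1"] == 3 and ref.sd["G1"] == pytest.approx(1 / np.sqrt(2))
        z = ors.zscores(expr, ref)
        np.testing.assert_allclose(
            z.values.loc["G1"], [(2 - 3) * np.sqrt(2), 2 * np.sqrt(2), 0.0]
        )

    def test_unscreenable_gene_requested_is_error(self):
        expr = _expr_from({"G1": [3, 3, 3]}, {"G1": [5.0]})
        ref = ors.reference_stats(expr)
        with pytest.raises(ScreenError, match="unscreenable"):
            ors.zscores(expr, ref, genes=["G1"])


class TestBurdenStats:
    def _z(self, rows: dict) -> ZScoreMatrix:
        cols = [f"T{i}" for i in range(len(next(iter(rows.values()))))]
        return ZScoreMatrix(pd.DataFrame(rows, index=cols).T, z_cut=2.0)

    def test_hand_oracle_single_gene(self):
        # Z = (2.5, 1.0, 3.0, -1.0): cohort = patients with any upregulation
        z = self._z({"G1": [2.5, 1.0, 3.0, -1.0]})
        b = ors.burden_stats(z)
        assert b.loc["G1", "n_upreg"] == 2
        assert b.loc["G1", "sum_upreg"] == pytest.approx(5.5)
        assert b.loc["G1", "weighted_upreg"] == pytest.approx(11.0)

    def test_sum_runs_over_cohort_of_any_upregulated(self):
        # a second gene pulls every patient into the cohort; sums span all m
        z = self._z({"G1": [2.5, 1.0, 3.0, -1.0], "G2": [2.1, 2.1, 2.1, 2.1]})
        b = ors.burden_stats(z)
        assert b.attrs["m"] == 4
        assert b.loc["G1", "sum_upreg"] == pytest.approx(5.5)  # incl. negatives
        assert b.loc["G1", "n_upreg"] == 2

    def test_all_below_cut_zero_weighted(self):
        z = self._z({"G1": [1.0, -1.0], "G2": [2.5, 0.0]})
        b = ors.burden_stats(z)
        assert b.loc["G1", "n_upreg"] == 0
        assert b.loc["G1", "weighted_upreg"] == 0.0

    def test_boundary_z_equal_cut_counts(self):
        # the indicator is 1 if Z >= 2, so exactly 2.0 is upregulated
        z = self._z({"G1": [2.0, 1.999999]})
        b = ors.burden_stats(z)
        assert b.loc["G1", "n_upreg"] == 1

    @pytest.mark.parametrize(
        "mode,expected_sum", [("all", 4.5), ("positive", 5.5), ("above_cut", 5.0)]
    )
    def test_sum_modes(self, mode, expected_sum):
        z = self._z({"G1": [2.0, 3.0, 0.5, -1.0], "G2": [2.1, 2.1, 2.1, 2.1]})
        b = ors.burden_stats(z, sum_mode=mode)
        assert b.loc["G1", "sum_upreg"] == pytest.approx(expected_sum)

    def test_empty_cohort_is_error(self):
        z = self._z({"G1": [0.0, 1.0]})
        with pytest.raises(ScreenError, match="empty cohort"):
            ors.burden_stats(z)

    def test_prevalence_uses_population_size(self):
        z = self._z({"G1": [2.5, 2.5, 0.0, 0.0]})
        b = ors.burden_stats(z, population_size=8)
        assert b.loc["G1", "prevalence"] == pytest.approx(0.25)

    @given(
        st.lists(
            st.lists(st.floats(-4, 8, allow_nan=False), min_size=4, max_size=8),
            min_size=1,
            max_size=5,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_weighted_identity_and_cut_monotonicity(self, rows):
        data = {f"G{i}": r for i, r in enumerate(rows)}
        z = self._z(data)
        if not (z.values >= 2.0).any().any():
            return
        b2 = ors.burden_stats(z, z_cut=2.0)
        # weighted = n * sum holds machine-exactly
        assert (b2["weighted_upreg"] == b2["n_upreg"] * b2["sum_upreg"]).all()
        if (z.values >= 3.0).any().any():
            b3 = ors.burden_stats(z, z_cut=3.0)
            assert (b3["n_upreg"] <= b2["n_upreg"]).all()


class TestThresholds:
    def _burden(self, values) -> pd.DataFrame:
        v = np.asarray(values, dtype=float)
        return pd.DataFrame(
            {"sum_upreg": v, "n_upreg": v, "weighted_upreg": v},
            index=[f"G{i}" for i in range(len(v))],
        )

    def test_mean_plus_1_6449_sd(self):
        # (8, 10, 12) has mean 10 and sample SD 2 -> threshold 13.2897
        thr = ors.significance_thresholds(self._burden([8, 10, 12]))
        assert thr.sum_threshold == pytest.approx(10 + 1.6449 * 2, abs=1e-3)

    def test_constant_statistic_threshold_equals_value(self, caplog):
        with caplog.at_level("WARNING"):
            thr = ors.significance_thresholds(self._burden([7, 7, 7]))
        assert thr.sum_threshold == 7
        assert "degenerate" in caplog.text

    def test_alpha_half_gives_mean(self):
        thr = ors.significance_thresholds(self._burden([8, 10, 12]), alpha=0.5)
        assert thr.sum_threshold == pytest.approx(10.0)

    def test_zero_padding_to_family_size(self):
        # padding with zero-burden genes shifts mean and SD
        b = self._burden([8, 10, 12])
        thr = ors.significance_thresholds(b, n_family=6)
        v = np.array([8, 10, 12, 0, 0, 0], dtype=float)
        assert thr.sum_threshold == pytest.approx(v.mean() + 1.6449 * v.std(ddof=1), abs=1e-3)

    def test_fewer_than_three_genes_rejected(self):
        with pytest.raises(ScreenError):
            ors.significance_thresholds(self._burden([1, 2]))


class TestSelectionAndFunnelPieces:
    def test_conjunction_required(self):
        b = pd.DataFrame(
            {
                "sum_upreg": [100.0, 1.0, 1.0],
                "n_upreg": [1.0, 1.0, 1.0],
                "weighted_upreg": [1.0, 1.0, 1.0],
            },
            index=["A", "B", "C"],
        )
        thr = ors.SignificanceThresholds(50.0, 10.0, 10.0, alpha=0.05)
        part1, part2, shared = ors.select_two_part(b, thr)
        assert part1 == set() and part2 == set() and shared == set()

    def test_all_below_thresholds_empty(self):
        b = pd.DataFrame(
            {"sum_upreg": [1.0, 2.0, 1.5], "n_upreg": [1, 1, 1],
             "weighted_upreg": [1.0, 2.0, 1.5]},
            index=["A", "B", "C"],
        )
        thr = ors.SignificanceThresholds(10.0, 10.0, 10.0, alpha=0.05)
        assert ors.select_two_part(b, thr) == (set(), set(), set())

    def test_high_amplification(self):
        cna = pd.DataFrame(
            {"S1": [2, 1, 0], "S2": [0, 1, 0]}, index=["A", "B", "C"]
        )
        assert ors.high_amplification_genes(cna) == {"A"}
        assert ors.high_amplification_genes(cna * 0) == set()

    def test_overexpressed_intersection(self):
        assert ors.overexpressed_set({"A", "B", "C"}, {"B", "C", "D"}) == {"B", "C"}
        assert ors.overexpressed_set({"A"}, set()) == set()

    def test_mutation_overlap(self, screened):
        _, truth, _, result = screened
        mut = pd.Series({"ORS300": 8, "ORS301": 6})
        assert ors.mutation_overlap(result, mut) == set()
        mut2 = pd.Series({g: 1 for g in list(result.overexpressed_genes)[:1]})
        assert ors.mutation_overlap(result, mut2) == set(mut2.index)
        assert ors.mutation_overlap(result, pd.Series(dtype=int)) == set()

    def test_prevalence_summary_hand_binning(self):
        b = pd.DataFrame({"prevalence": [0.01, 0.02, 0.11]})
        out = ors.prevalence_summary(b, bins=(0.05, 0.10))
        assert out.to_list() == [2, 0, 1]
        empty = ors.prevalence_summary(pd.DataFrame({"prevalence": []}))
        assert (empty == 0).all()


class TestFullScreen:
    def test_fixture_recovers_planted(self, screened):
        _, truth, _, result = screened
        assert result.overexpressed_genes == set(truth.overexpressed)
        assert result.overexpressed_genes <= result.shared_genes
        assert result.shared_genes <= result.part1_genes
        assert result.shared_genes <= result.part2_genes

    def test_positive_case_flags_cover_carriers(self, screened):
        _, truth, _, result = screened
        carriers = {c for cars in truth.carriers.values() for c in cars}
        flagged = set(result.positive_cases)
        # nearly every carrier shows z >= 2 in its planted gene
        assert len(carriers - flagged) <= 0.02 * len(carriers)

    def test_downregulation_mirror(self, three_subpop):
        bundle, _ = three_subpop
        _, result = screen_bundle(bundle, direction="down")
        # planted effects are upregulation only: the mirrored screen is empty
        assert result.direction == "down"
        assert result.overexpressed_genes == set()

    def test_down_indicator_counts_negative_tail(self):
        expr = _expr_from(
            {"G1": [0.0, 1.0, -1.0, 0.5], "G2": [0.0, 1.0, -1.0, 0.5],
             "G3": [0.0, 1.0, -1.0, 0.5]},
            {"G1": [-3.0, -2.5], "G2": [0.0, 0.1], "G3": [0.2, 0.0]},
        )
        cna = pd.DataFrame({"T0": [0, 0, 0], "T1": [0, 0, 0]},
                           index=["G1", "G2", "G3"])
        res = ors.run_screen(expr, cna, ["G1", "G2", "G3"], direction="down")
        assert res.burden.loc["G1", "n_upreg"] == 2  # two cases at Z <= -2

    def test_amplified_superset_monotonicity(self, screened):
        # enlarging the amplified set can only grow the over-expressed set
        _, _, _, result = screened
        bigger = ors.overexpressed_set(
            result.shared_genes, result.amplified_genes | {"ORS999"}
        )
        assert result.overexpressed_genes <= bigger

    def test_diagnostics_reports_all_sum_modes(self, three_subpop):
        bundle, truth = three_subpop
        cm, _ = ors.align_genes(bundle.counts, bundle.annotation)
        expr = ors.log2_transform(ors.compute_fpkm(cm, bundle.annotation))
        fam = list(bundle.annotation.index[bundle.annotation["family"] == "OR"])
        diag = ors.screen_diagnostics(expr, bundle.cna, fam)
        assert list(diag.index) == ["all", "positive", "above_cut"]
        assert (diag["overexpressed"] == len(truth.overexpressed)).all()
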