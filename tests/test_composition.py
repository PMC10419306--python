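import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scstate.composition import (
    InsufficientDonorsError,
    classify_tier,
    composition_report,
    grubbs_critical_value,
    grubbs_test,
    proportion_table,
    student_t_test,
)


def cells_frame(spec):
    """spec: list of (donor, condition, cell_type, n, is_subtype)."""
    rows = []
    for donor, condition, cell_type, n, is_sub in spec:
        for i in range(n):
            rows.append(
                {
                    "barcode": f"{donor}_{cell_type}_{is_sub}_{i}",
                    "donor": donor,
                    "condition": condition,
                    "cell_type": cell_type,
                    "is_subtype": is_sub,
                }
            )
    return pd.DataFrame(rows)


class TestProportionTable:
    def test_single_donor_proportions(self):
        cells = cells_frame([("d1", "control", "A", 30, False), ("d1", "control", "B", 70, False)])
        pt = proportion_table(cells).set_index("cell_type")
        assert pt.loc["A", "proportion"] == pytest.approx(0.3)
        assert pt.loc["B", "proportion"] == pytest.approx(0.7)

    def test_subtype_denominator_is_parent_population(self):
        cells = cells_frame(
            [("d1", "disease", "T", 93, False), ("d1", "disease", "T", 7, True),
             ("d1", "disease", "B", 100, False)]
        )
        pt = proportion_table(cells, level="is_subtype", parent="T")
        gated = pt[pt["cell_type"] == True]  # noqa: E712
        assert gated["proportion"].iloc[0] == pytest.approx(0.07)

    def test_per_donor_sums_to_one(self, sim_run):
        _, _, cells, _ = sim_run
        pt = proportion_table(cells)
        assert np.allclose(pt.groupby("donor")["proportion"].sum(), 1.0, atol=1e-12)

    def test_matches_simulation_truth_within_sampling_error(self, sim_run):
        _, _, cells, truth = sim_run
        pt = proportion_table(cells).set_index(["donor", "cell_type"])["proportion"]
        tp = truth.proportions.set_index(["donor", "cell_type"])["proportion"]
        assert np.allclose(pt.sort_index(), tp.sort_index(), atol=1e-12)

    def test_donor_with_no_cells_at_level_excluded_with_warning(self):
        cells = cells_frame(
            [("d1", "control", "T", 10, False), ("d2", "control", "B", 10, False)]
        )
        with pytest.warns(UserWarning, match="d2"):
            pt = proportion_table(cells, level="cell_type", parent="T")
        assert set(pt["donor"]) == {"d1"}


class TestStudentT:
    def test_equal_means_with_variance_give_t_zero_p_one(self):
        res = student_t_test([0.1, 0.3], [0.3, 0.1])
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_distinct_means_degenerate_convention(self):
        res = student_t_test([0.1, 0.1], [0.3, 0.3])
        assert res.zero_variance and res.p == 0.0 and res.t == -np.inf

    def test_hand_computed_example(self):
        res = student_t_test([0.10, 0.12, 0.11, 0.13], [0.20, 0.22, 0.21, 0.23])
        assert res.t == pytest.approx(-10.954, abs=5e-3)
        assert res.p == pytest.approx(2 * stats.t.sf(10.954451, 6), rel=1e-4)
        assert res.p == pytest.approx(3.5e-5, rel=0.05)
        assert classify_tier(res.p) == "*"

    def test_insufficient_donors_raises(self):
        with pytest.raises(InsufficientDonorsError):
            student_t_test([0.1], [0.2, 0.3])

    def test_antisymmetric_in_t_same_p_under_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 1, 5), rng.uniform(0, 1, 6)
        r1, r2 = student_t_test(a, b), student_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)


class TestTiers:
    @pytest.mark.parametrize(
        "p,tier",
        [(0.04, "*"), (0.049999, "*"), (0.05, "‡"), (0.07, "‡"), (0.09999, "‡"), (0.1, "n.s."), (0.5, "n.s.")],
    )
    def test_tier_boundaries(self, p, tier):
        assert classify_tier(p) == tier


class TestGrubbs:
    def test_textbook_outlier_flagged(self):
        assert grubbs_test([1, 1, 1, 10], alpha=0.05) == 3

    def test_symmetric_small_sample_not_flagged(self):
        assert grubbs_test([1, 2, 3], alpha=0.05) is None

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            grubbs_test([2, 2, 2, 2])

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError, match="n >= 3"):
            grubbs_test([1, 2])

    def test_critical_values_match_t_distribution_closed_form(self):
        for n in range(3, 31):
            t = stats.t.ppf(1 - 0.05 / (2 * n), n - 2)
            expected = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
            assert grubbs_critical_value(n, 0.05) == pytest.approx(expected, abs=1e-6)

    def test_published_reference_values(self):
        # standard two-sided 5% table: n=3 -> 1.1543, n=4 -> 1.4812
        assert grubbs_critical_value(3) == pytest.approx(1.1543, abs=1e-4)
        assert grubbs_critical_value(4) == pytest.approx(1.4812, abs=1e-4)

    def test_affine_invariance_of_the_decision(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=8)
        x[3] += 8
        for a, b in [(2.5, 0.0), (0.3, -7.0), (10.0, 100.0)]:
            assert grubbs_test(a * x + b) == grubbs_test(x)


class TestCompositionReport:
    def test_planted_twofold_shift_is_tiered_significant(self):
        from scstate.synthetic import default_fixture, simulate_composition

        pt = simulate_composition(default_fixture(seed=17))
        report = composition_report(pt).set_index("cell_type")
        assert report.loc["T_cell", "tier"] == "*"
        assert report.loc["T_cell", "fold_change"] > 1.2

    def test_outlier_donor_removed_and_logged(self):
        from scstate.synthetic import default_fixture, simulate_composition

        pt = simulate_composition(default_fixture(seed=17, outlier=True))
        report = composition_report(pt).set_index("cell_type")
        assert "ctrl1 (control)" in report.loc["T_cell", "removed_donors"]

    def test_single_gated_control_donor_removed_then_insufficient(self):
        # one control donor contributes the only nonzero subtype proportion;
        # Grubbs removes it and the comparison is reported as insufficient
        pt = pd.DataFrame(
            {
                "donor": ["c1", "c2", "c3", "c4", "d1", "d2", "d3", "d4"],
                "condition": ["control"] * 4 + ["disease"] * 4,
                "cell_type": ["sub"] * 8,
                "n_cells": [1, 0, 0, 0, 5, 6, 7, 8],
                "proportion": [0.02, 0.0, 0.0, 0.0, 0.05, 0.06, 0.07, 0.08],
            }
        )
        report = composition_report(pt, nonzero_only=True)
        row = report.iloc[0]
        assert "c1 (control)" in row["removed_donors"]
        assert row["note"].startswith("insufficient donors")
        assert row["tier"] == ""

    def test_errors_recorded_per_cell_type_not_raised(self):
        pt = pd.DataFrame(
            {
                "donor": ["c1", "d1", "d2"],
                "condition": ["control", "disease", "disease"],
                "cell_type": ["A"] * 3,
                "n_cells": [1, 1, 1],
                "proportion": [0.5, 0.5, 0.5],
            }
        )
        report = composition_report(pt)
        assert report.loc[0, "note"].startswith("insufficient donors")
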