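"""Fraction arithmetic, the linear distance null, sectioning bias."""

import numpy as np
import pandas as pd
import pytest

from capsidkit.scenes import SceneSpec, _sample_positions, simulate_maturation_records
from capsidkit.stats import (
    StatsError,
    TYPE_ORDER,
    combine_fractions,
    distance_fit_test,
    linear_null_expected,
    slab_bias,
    timecourse_table,
    type_fractions,
)

#: printed observations used as fixed inputs
TOMOGRAM_COUNTS = {"Full": 20, "s-Full": 3, "p-Empty": 7, "Empty": 105}
TOMOGRAM_FRACTIONS = {"Full": 14.8, "s-Full": 2.2, "p-Empty": 5.2, "Empty": 77.8}
THIN_18HPI_FRACTIONS = {"Full": 17.4, "s-Full": 1.3, "p-Empty": 5.4, "Empty": 75.8}
OUTSIDE_FRACTIONS = {"p-Empty": 28.0, "Empty": 22.0, "s-Full": 8.0, "Full": 38.0}


class TestFractions:
    def test_tomogram_counts(self):
        table = type_fractions(TOMOGRAM_COUNTS)
        assert table.row("all") == TOMOGRAM_FRACTIONS

    def test_single_count(self):
        assert type_fractions({"Full": 1}).row("all") == {
            "Full": 100.0, "s-Full": 0.0, "p-Empty": 0.0, "Empty": 0.0,
        }

    def test_empty_group_raises(self):
        with pytest.raises(StatsError):
            type_fractions({})

    def test_thin_vs_tomogram_max_difference(self):
        """The 70-nm thin-section fractions at 18 hpi differ from the
        whole-particle tomogram fractions by at most 2.6 points."""
        diffs = [
            abs(THIN_18HPI_FRACTIONS[t] - TOMOGRAM_FRACTIONS[t])
            for t in TYPE_ORDER
        ]
        assert max(diffs) == pytest.approx(2.6)

    def test_combined_outside_cell(self):
        assert combine_fractions(OUTSIDE_FRACTIONS, ["p-Empty", "Empty"]) == 50.0
        assert combine_fractions(OUTSIDE_FRACTIONS, ["Full", "s-Full"]) == 46.0
        assert combine_fractions(OUTSIDE_FRACTIONS, []) == 0.0

    def test_combine_unknown_type(self):
        with pytest.raises(StatsError):
            combine_fractions(OUTSIDE_FRACTIONS, ["Fullish"])


class TestLinearNull:
    def test_zero_radius(self):
        np.testing.assert_allclose(
            linear_null_expected(0.0, [0, 1, 2], 100), [25.0, 75.0]
        )

    def test_flat_limit(self):
        np.testing.assert_allclose(
            linear_null_expected(np.inf, [0, 0.5, 1, 1.5, 2], 100), [25.0] * 4
        )

    def test_sums_to_total_exactly(self):
        exp = linear_null_expected(5.0, np.arange(0, 2.1, 0.5), 1234)
        assert exp.sum() == pytest.approx(1234, abs=1e-9)

    def test_matches_monte_carlo(self):
        a, n = 5.0, 10000
        spec = SceneSpec(nucleus_radius_um=a, cell_radius_um=12.0, counts={},
                         max_distance_um=2.0)
        pos = _sample_positions(spec, n, np.random.default_rng(0))
        d = np.hypot(pos[:, 0], pos[:, 1]) - a
        edges = np.arange(0, 2.01, 0.5)
        obs, _ = np.histogram(d, bins=edges)
        exp = linear_null_expected(a, edges, n)
        assert (np.abs(obs - exp) < 3 * np.sqrt(exp)).all()

    def test_invalid_inputs(self):
        with pytest.raises(StatsError):
            linear_null_expected(5.0, [0, 1], 0)
        with pytest.raises(StatsError):
            linear_null_expected(-1.0, [0, 1], 10)
        with pytest.raises(StatsError):
            linear_null_expected(5.0, [2, 1], 10)


class TestDistanceFit:
    def _frame(self, d, typ="Empty"):
        return pd.DataFrame({"true_type": typ, "distance_um": d})

    def test_observed_equals_expected(self):
        a = 5.0
        edges = np.arange(0, 2.01, 0.5)
        exp = linear_null_expected(a, edges, 400).round().astype(int)
        d = np.concatenate(
            [np.full(c, lo + 0.25) for c, lo in zip(exp, edges[:-1])]
        )
        res = distance_fit_test(self._frame(d), a)
        row = res.per_type.loc["Empty"]
        assert row.statistic == pytest.approx(0.0, abs=0.05)
        assert row.p_value > 0.99

    def test_merging_is_deterministic_and_applied(self):
        # tiny sample forces merging of low-expectation bins
        d = np.array([0.1, 0.3, 1.9])
        res = distance_fit_test(self._frame(d), 0.001)
        assert res.per_type.loc["Empty", "dof"] >= 1

    def test_window_exclusion(self):
        d = np.array([0.2, 0.4, 5.0, 7.0, 0.6, 1.2, 1.8, 0.9])
        res = distance_fit_test(self._frame(d), 5.0)
        assert res.per_type.loc["Empty", "n"] == 6

    def test_no_usable_records(self):
        with pytest.raises(StatsError):
            distance_fit_test(self._frame(np.array([5.0, 9.0])), 5.0)


@pytest.fixture(scope="module")
def bias70():
    return slab_bias(70.0, n_per_type=150, seed=0)


class TestSlabBias:
    def test_rows_sum_to_one(self, bias70):
        np.testing.assert_allclose(bias70.confusion.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_no_hallucinated_nucleoid(self, bias70):
        """A DNA-free particle is never typed as Full, and misclassified
        mass never flows from Empty into the DNA classes."""
        c = bias70.confusion
        assert c.loc["Empty", "Full"] == 0.0
        assert c.loc["Empty", "s-Full"] == 0.0
        assert c.loc["p-Empty", "Full"] == 0.0

    def test_apply_roundtrip_identity_like(self, bias70):
        pred = bias70.apply(TOMOGRAM_FRACTIONS)
        assert sum(pred.values()) == pytest.approx(100.0, abs=0.3)

    def test_bias_correction_nonnegative(self, bias70):
        corrected = bias70.correct(TOMOGRAM_FRACTIONS)
        assert all(v >= 0 for v in corrected.values())
        assert sum(corrected.values()) == pytest.approx(100.0, abs=0.3)

    def test_invalid_n(self):
        with pytest.raises(StatsError):
            slab_bias(70.0, n_per_type=0)


class TestTimecourse:
    def test_single_group_reduces_to_fractions(self):
        recs = simulate_maturation_records(200, [18.0], seed=0)
        table = timecourse_table(recs, min_count=10)
        assert list(table.fractions.index) == [18.0]
        assert table.fractions.loc[18.0].sum() == pytest.approx(100.0, abs=0.3)

    def test_printed_18hpi_row(self):
        frame = pd.DataFrame(
            {
                "true_type": [t for t, n in TOMOGRAM_COUNTS.items()
                              for _ in range(n)],
                "hpi": 18.0,
            }
        )
        table = timecourse_table(frame, min_count=10)
        assert table.row(18.0) == TOMOGRAM_FRACTIONS

    def test_small_groups_dropped(self):
        frame = pd.DataFrame(
            {
                "true_type": ["Full"] * 30 + ["Empty"] * 3,
                "hpi": [10.0] * 30 + [6.0] * 3,
            }
        )
        table = timecourse_table(frame, min_count=20)
        assert list(table.fractions.index) == [10.0]

    def test_no_hpi_raises(self):
        with pytest.raises(StatsError):
            timecourse_table(pd.DataFrame({"true_type": ["Full"]}))
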