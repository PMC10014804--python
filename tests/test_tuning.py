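"""Per-unit tuning statistics: index, curves, MD, PD, circular distance, cc."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilat import (
    TuningCurve,
    bilateral_correlation,
    bimanual_marginal_curve,
    circular_diff,
    classify_quadrants,
    cosine_fit_pd,
    md_difference_stats,
    modulation_depth,
    preference_index,
    preferred_direction,
    strong_cc_fraction,
)

DIRS4 = np.array([45.0, 135.0, 225.0, 315.0])
DIRS8 = np.arange(0.0, 360.0, 45.0)


def _curve(values, arm="ipsi", task=None, dirs=None):
    values = np.asarray(values, float)
    if dirs is None:
        dirs = DIRS8 if len(values) == 8 else DIRS4
    if task is None:
        task = "unimanual-8" if len(values) == 8 else "bimanual-4"
    return TuningCurve(arm=arm, task=task, dirs_deg=dirs, values_hz=values)


class TestPreferenceIndex:
    def test_pure_contralateral_is_plus_one(self):
        assert preference_index(5.0, 0.0) == 1.0

    def test_pure_ipsilateral_is_minus_one(self):
        assert preference_index(0.0, 5.0) == -1.0

    def test_equal_arms_is_zero(self):
        assert preference_index(5.0, 5.0) == 0.0

    def test_direct_evaluation(self):
        assert preference_index(3.0, 1.0) == pytest.approx(0.5)

    def test_both_zero_is_undefined_sentinel(self):
        assert np.isnan(preference_index(0.0, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            preference_index(-1.0, 2.0)

    @settings(max_examples=100, derandomize=True)
    @given(c=st.floats(0, 1e6), i=st.floats(1e-9, 1e6))
    def test_antisymmetric_under_arm_swap(self, c, i):
        assert preference_index(c, i) == pytest.approx(-preference_index(i, c), abs=1e-12)
        assert -1.0 <= preference_index(c, i) <= 1.0


class TestMarginalCurve:
    @staticmethod
    def _grid(fn):
        rows = [
            dict(ipsi_dir_deg=di, contra_dir_deg=dc, response_hz=fn(di, dc))
            for di in DIRS4
            for dc in DIRS4
        ]
        return pd.DataFrame(rows)

    def test_worked_grid_matches_hand_averages(self):
        rng = np.random.default_rng(42)
        values = {(di, dc): rng.normal() for di in DIRS4 for dc in DIRS4}
        grid = self._grid(lambda di, dc: values[(di, dc)])
        curve = bimanual_marginal_curve(grid, "ipsi")
        for k, d in enumerate(DIRS4):
            expected = sum(values[(d, dc)] for dc in DIRS4) / 4.0  # explicit 4-term mean
            assert curve.values_hz[k] == pytest.approx(expected)

    def test_additive_responses_recover_component_plus_constant(self):
        f_i = {45.0: 1.0, 135.0: -2.0, 225.0: 0.5, 315.0: 3.0}
        f_c = {45.0: 2.0, 135.0: 1.0, 225.0: -1.0, 315.0: 0.0}
        grid = self._grid(lambda di, dc: f_i[di] + f_c[dc])
        curve = bimanual_marginal_curve(grid, "ipsi")
        const = np.mean(list(f_c.values()))
        assert curve.values_hz == pytest.approx([f_i[d] + const for d in DIRS4])

    def test_constant_grid_gives_constant_marginals(self):
        grid = self._grid(lambda di, dc: 3.3)
        for arm in ("ipsi", "contra"):
            assert bimanual_marginal_curve(grid, arm).values_hz == pytest.approx([3.3] * 4)

    def test_missing_configuration_rejected(self):
        grid = self._grid(lambda di, dc: 0.0).iloc[:-1]
        with pytest.raises(ValueError):
            bimanual_marginal_curve(grid, "ipsi")


class TestModulationDepth:
    def test_constant_curve_is_zero(self):
        assert modulation_depth(_curve([2.0] * 8)) == 0.0

    def test_max_minus_min(self):
        assert modulation_depth(_curve([1.0, 5.0, -2.0, 3.0])) == 7.0

    def test_on_grid_cosine_spans_twice_the_amplitude(self):
        m, pd_deg = 3.7, 90.0
        vals = m * np.cos(np.deg2rad(DIRS8 - pd_deg))
        assert modulation_depth(_curve(vals)) == pytest.approx(2 * m)

    @settings(max_examples=50, derandomize=True)
    @given(
        shift=st.floats(-100, 100), gain=st.floats(0, 50),
        vals=st.lists(st.floats(-50, 50), min_size=4, max_size=4),
    )
    def test_shift_invariant_and_gain_linear(self, shift, gain, vals):
        base = modulation_depth(_curve(vals))
        assert modulation_depth(_curve(np.array(vals) + shift)) == pytest.approx(base, abs=1e-9)
        assert modulation_depth(_curve(gain * np.array(vals))) == pytest.approx(gain * base, rel=1e-9, abs=1e-9)


class TestPreferredDirection:
    def test_unique_maximum(self):
        vals = [0.0, 0.0, 4.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        assert preferred_direction(_curve(vals)) == (90.0, False)

    def test_tie_broken_toward_smallest_angle_and_flagged(self):
        vals = [4.0, 0.0, 0.0, 0.0, 4.0, 0.0, 0.0, 0.0]
        assert preferred_direction(_curve(vals)) == (0.0, True)

    def test_cosine_fit_recovers_off_grid_pd(self):
        vals = 2.0 * np.cos(np.deg2rad(DIRS8 - 60.0)) + 1.0
        pd_deg, amp = cosine_fit_pd(_curve(vals))
        assert pd_deg == pytest.approx(60.0, abs=1e-6)
        assert amp == pytest.approx(2.0, abs=1e-6)


class TestCircularDiff:
    @pytest.mark.parametrize(
        "a,b,expected", [(0, 0, 0), (0, 270, 90), (45, 225, 180), (350, 10, 20)]
    )
    def test_examples(self, a, b, expected):
        assert circular_diff(a, b) == expected

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.floats(0, 359.99), b=st.floats(0, 359.99), c=st.floats(0, 359.99)
    )
    def test_metric_properties(self, a, b, c):
        assert circular_diff(a, b) == circular_diff(b, a)
        assert 0 <= circular_diff(a, b) <= 180
        assert circular_diff(a, c) <= circular_diff(a, b) + circular_diff(b, c) + 1e-9

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            circular_diff(360.0, 0.0)


class TestBilateralCorrelation:
    def test_positive_affine_relation_gives_one(self):
        x = _curve([1.0, 3.0, -2.0, 0.5], arm="ipsi")
        y = _curve(2.0 * x.values_hz + 1.0, arm="contra")
        assert bilateral_correlation(x, y) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        x = _curve([1.0, 3.0, -2.0, 0.5], arm="ipsi")
        y = _curve(-x.values_hz, arm="contra")
        assert bilateral_correlation(x, y) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        xv, yv = np.array([1.0, 2.0, 3.0, 5.0]), np.array([2.0, 1.0, 4.0, 4.0])
        # covariance-formula oracle
        dx, dy = xv - xv.mean(), yv - yv.mean()
        expected = (dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum())
        got = bilateral_correlation(_curve(xv, arm="ipsi"), _curve(yv, arm="contra"))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_curve_is_undefined_sentinel(self):
        x = _curve([1.0, 1.0, 1.0, 1.0], arm="ipsi")
        y = _curve([1.0, 2.0, 3.0, 4.0], arm="contra")
        assert np.isnan(bilateral_correlation(x, y))

    def test_grid_mismatch_rejected(self):
        x = _curve([1.0, 2.0, 3.0, 4.0], arm="ipsi", task="unimanual-4", dirs=DIRS4)
        y = _curve([1.0, 2.0, 3.0, 4.0], arm="contra", task="unimanual-4", dirs=np.array([0.0, 90.0, 180.0, 270.0]))
        with pytest.raises(ValueError):
            bilateral_correlation(x, y)


class TestClassifications:
    def test_planted_quadrants_match_construction(self):
        df = pd.DataFrame(
            dict(
                unit_id=[f"u{i}" for i in range(6)],
                uni_index=[0.5, 0.5, -0.5, -0.5, 0.0, np.nan],
                bi_index=[0.5, -0.5, 0.5, -0.5, 0.5, 0.1],
            )
        )
        per_unit, counts = classify_quadrants(df)
        assert len(per_unit) == 5  # NaN unit excluded
        got = counts.set_index("quadrant")["n"].to_dict()
        # index exactly 0 counts as ipsilateral-preferring
        assert got == {"contra→contra": 1, "contra→ipsi": 1, "ipsi→contra": 2, "ipsi→ipsi": 1}
        assert counts["fraction"].sum() == pytest.approx(1.0)

    def test_all_contra_units(self):
        df = pd.DataFrame(dict(unit_id=["a", "b"], uni_index=[0.1, 0.9], bi_index=[0.2, 0.3]))
        _, counts = classify_quadrants(df)
        assert counts.set_index("quadrant").loc["contra→contra", "fraction"] == 1.0

    def test_strong_cc_fraction_is_strict(self):
        assert strong_cc_fraction([0.75, 0.76, 0.2, np.nan]) == pytest.approx(1 / 3)
        assert np.isnan(strong_cc_fraction([np.nan]))

    def test_md_difference_planted_offset(self):
        summary = pd.DataFrame(
            dict(
                unit_id=[f"u{i}" for i in range(10)],
                task=["bimanual-4"] * 10,
                md_ipsi_hz=np.linspace(1, 5, 10),
                md_contra_hz=np.linspace(1, 5, 10) + 2.0,
            )
        )
        stats = md_difference_stats(summary)
        assert stats.loc[0, "mean_diff_hz"] == pytest.approx(2.0)
        assert stats.loc[0, "median_diff_hz"] == pytest.approx(2.0)
        assert stats.loc[0, "n_contra_larger"] == 10

    def test_md_difference_antisymmetric_cohort_has_zero_median(self):
        summary = pd.DataFrame(
            dict(
                unit_id=[f"u{i}" for i in range(5)],
                task=["unimanual-8"] * 5,
                md_ipsi_hz=[1.0, 2.0, 3.0, 4.0, 5.0],
                md_contra_hz=[5.0, 4.0, 3.0, 2.0, 1.0],
            )
        )
        assert md_difference_stats(summary).loc[0, "median_diff_hz"] == 0.0
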