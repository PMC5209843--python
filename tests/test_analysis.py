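"""Term selection, period selection, leaf choice and group statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from leafrhythm import GroupSizeError, TimeSeries
from leafrhythm.rhythm import (CosineComponent, add_terms, analyze_series,
                               choose_leaf, compare_groups, detrend,
                               select_period)
from leafrhythm.rhythm.analyze import RhythmFit
from leafrhythm.synthetic import SimulationSpec, simulate_series


def detrended(series):
    out, _ = detrend(series)
    return out


class TestAddTerms:
    def test_pure_cosine_keeps_exactly_one_term(self):
        series, _ = simulate_series(
            SimulationSpec(period_h=24, noise_frac=0, phase_h=6))
        comps, sse, _ = add_terms(detrended(series), (15, 35))
        assert len(comps) == 1
        assert comps[0].period == pytest.approx(24.0, rel=1e-6)

    def test_two_component_signal_recovered(self):
        t = np.arange(721) / 6
        y = 10 * np.cos(2 * np.pi * t / 24) + 3 * np.cos(2 * np.pi * (t - 2) / 12)
        comps, sse, _ = add_terms(detrended(TimeSeries(t, y)), (15, 35))
        periods = sorted(c.period for c in comps)
        assert len(comps) == 2
        assert periods[0] == pytest.approx(12.0, rel=0.01)
        assert periods[1] == pytest.approx(24.0, rel=0.01)

    def test_white_noise_terminates_early(self):
        rng = np.random.default_rng(5)
        t = np.arange(721) / 6
        y = rng.normal(0, 1, size=len(t))
        comps, sse, _ = add_terms(detrended(TimeSeries(t, y)), (15, 35))
        assert len(comps) < 4
        # the retained terms explain almost nothing of the noise energy
        assert sse > 0.8 * float(y @ y)


class TestSelectPeriod:
    def test_singleton(self):
        c = CosineComponent(10, 24, 3)
        assert select_period([c], [0.01], (15, 35)) is c

    def test_window_excludes_out_of_range_term(self):
        c24 = CosineComponent(5, 24.1, 0)
        c12 = CosineComponent(9, 11.9, 0)
        best = select_period([c24, c12], [0.01, 0.05], (15, 35))
        assert best is c24

    def test_all_above_ceiling_is_arrhythmic(self):
        comps = [CosineComponent(5, 24, 0), CosineComponent(3, 26, 0)]
        assert select_period(comps, [0.2, 0.5], (15, 35)) is None

    def test_tie_breaks_towards_larger_amplitude(self):
        small = CosineComponent(2, 23, 0)
        large = CosineComponent(8, 25, 0)
        assert select_period([small, large], [0.01, 0.01], (15, 35)) is large


class TestChooseLeaf:
    def _fit(self, period=None):
        fit = RhythmFit(trend=(0.0, 0.0))
        fit.selected_period = period
        return fit

    def test_left_preferred_over_right(self):
        pick = choose_leaf(self._fit(24.2), self._fit(23.1))
        assert pick.selected_period == 24.2

    def test_right_as_fallback(self):
        pick = choose_leaf(self._fit(None), self._fit(23.1))
        assert pick.selected_period == 23.1

    def test_both_arrhythmic_excluded(self):
        assert choose_leaf(self._fit(None), self._fit(None)) is None


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups({"a": [24, 25, 23], "b": [24, 25, 23]})
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_exact_separation(self):
        res = compare_groups({"wt": [24, 24, 24], "mut": [23, 23, 23]})
        assert res.p_value < 1e-6
        assert res.t_statistic > 0

    def test_matches_scipy_student_t(self, rng):
        xa = rng.normal(24.5, 0.8, size=12)
        xb = rng.normal(23.4, 0.6, size=9)
        res = compare_groups({"a": xa, "b": xb})
        t_ref, p_ref = sps.ttest_ind(xa, xb, equal_var=True)
        assert res.t_statistic == pytest.approx(float(t_ref))
        assert res.p_value == pytest.approx(float(p_ref))
        assert res.df == 19
        assert res.n == (12, 9)

    def test_group_size_errors(self):
        with pytest.raises(GroupSizeError):
            compare_groups({"a": [24, 24], "b": [23]})
        with pytest.raises(GroupSizeError):
            compare_groups({"a": [24, 24]})
        with pytest.raises(GroupSizeError):
            compare_groups({"a": [1, 2], "b": [1, 2], "c": [1, 2]})


class TestAnalyzeSeries:
    def test_white_noise_is_arrhythmic(self):
        rng = np.random.default_rng(8)
        t = np.arange(721) / 6
        fit = analyze_series(TimeSeries(t, rng.normal(0, 5, size=len(t))))
        assert fit.status == "arrhythmic"
        assert fit.selected_period is None

    def test_components_sorted_by_relative_error(self):
        series, _ = simulate_series(SimulationSpec(period_h=24, seed=2))
        fit = analyze_series(series)
        finite = [e for e in fit.rel_err if np.isfinite(e)]
        assert finite == sorted(finite)
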