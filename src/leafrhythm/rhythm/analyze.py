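"""Full rhythm analysis of one tip-position series.

Pipeline: detrend -> FFT seed -> greedy multi-cosine Gauss-Newton fit ->
support-plane relative errors -> least-relative-error period selection.
A trace for which no component passes the period window and the reliability
ceiling is reported as arrhythmic (a value, not an error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..config import Config
from ..errors import ConvergenceError, NoCandidateError
from ..series import TimeSeries
from .ci import period_relative_errors
from .fit import gn_minimize, sse_of_params
from .model import (CosineComponent, components_to_params, evaluate_params,
                    params_to_components)
from .seed import detrend, fft_seed

#: Residual floor (relative to the signal energy) below which the fit is
#: treated as exact and no further terms are added.
RESIDUAL_FLOOR = 1e-10


@dataclass
class RhythmFit:
    """Result of fitting one series.

    Components are sorted by ascending relative error of their period;
    ``selected_period`` is None for an arrhythmic trace.
    """

    trend: tuple[float, float]                 # (slope px/h, intercept px)
    components: list[CosineComponent] = field(default_factory=list)
    rel_err: list[float] = field(default_factory=list)
    sse: float = float("nan")
    selected_period: float | None = None
    selected_phase: float | None = None
    selected_amplitude: float | None = None

    @property
    def status(self) -> str:
        return "ok" if self.selected_period is not None else "arrhythmic"

    @property
    def n_terms(self) -> int:
        return len(self.components)


def add_terms(
    series: TimeSeries, window: tuple[float, float], max_terms: int = 4,
    term_var_threshold: float = 0.1,
) -> tuple[list[CosineComponent], float, tuple[float, float]]:
    """Greedy forward selection of cosine terms on a detrended series.

    The first term is the strongest spectral candidate inside the circadian
    window.  Each further candidate is the strongest peak of the current
    residual spectrum at any resolvable period (so harmonics can be
    absorbed); it is kept only if the joint refit reduces the current
    residual sum of squares by at least ``term_var_threshold`` of its value.
    A small affine correction (intercept, slope) is fitted jointly with the
    cosines, because linear pre-detrending leaves a residual affine
    component (finite-window cosines are not orthogonal to lines); it is
    returned as the third element and belongs to the trend, not the rhythm.

    Returns ``(components, sse, (intercept, slope))``.

    Raises
    ------
    NoCandidateError
        If not even the first in-window candidate exists.
    """
    t, y = series.dropna()
    seeds = fft_seed(series, window, max_candidates=1)
    params0 = np.concatenate([components_to_params(seeds[:1]), [0.0, 0.0]])
    params, sse = gn_minimize(t, y, params0, affine=True)
    energy = float(y @ y)

    while (len(params) - 2) // 3 < max_terms:
        if sse <= RESIDUAL_FLOOR * max(energy, 1e-300):
            break
        resid = y - evaluate_params(params, t, affine=True)
        resid_full = np.full_like(series.y, np.nan)
        resid_full[series.valid] = resid
        resid_series = series.replace(resid_full)
        try:
            cand = fft_seed(resid_series, None, max_candidates=1)[0]
        except NoCandidateError:
            break
        trial0 = np.concatenate([params[:-2], components_to_params([cand]),
                                 params[-2:]])
        try:
            trial, trial_sse = gn_minimize(t, y, trial0, affine=True)
        except ConvergenceError:
            break  # candidate cannot be fitted jointly: reject it
        explained = (sse - trial_sse) / sse if sse > 0 else 0.0
        if explained < term_var_threshold:
            break
        params, sse = trial, trial_sse
    return params_to_components(params, affine=True), sse, \
        (float(params[-2]), float(params[-1]))


def select_period(components: list[CosineComponent], rel_err: list[float],
                  window: tuple[float, float],
                  ceiling: float = 0.15) -> CosineComponent | None:
    """Least-relative-error component inside the window, or None.

    Only components whose period lies in the circadian window and whose
    relative error is below the reliability ceiling qualify; ties on
    relative error are broken towards the larger amplitude (the term with
    the most impact on the fit).
    """
    lo, hi = window
    eligible = [(e, -c.amplitude, c) for c, e in zip(components, rel_err)
                if lo <= c.period <= hi and e <= ceiling]
    if not eligible:
        return None
    eligible.sort(key=lambda item: (item[0], item[1]))
    return eligible[0][2]


def analyze_series(series: TimeSeries, config: Config | None = None) -> RhythmFit:
    """Detrend, fit and classify one tip-position series."""
    config = config or Config()
    detrended, trend = detrend(series, config.detrend, config.ma_window_h)
    try:
        components, sse, affine = add_terms(detrended, config.period_window,
                                            config.max_terms,
                                            config.term_var_threshold)
    except NoCandidateError:
        return RhythmFit(trend=trend, sse=float("nan"))
    trend = (trend[0] + affine[1], trend[1] + affine[0])

    t, y = detrended.dropna()
    params = np.concatenate([components_to_params(components), affine])
    rel = period_relative_errors(t, y, params,
                                 sse_of_params(params, t, y, affine=True),
                                 alpha=config.alpha, affine=True)
    order = np.argsort(rel, kind="stable")
    components = [components[i] for i in order]
    rel_sorted = [float(rel[i]) for i in order]

    fit = RhythmFit(trend=trend, components=components, rel_err=rel_sorted, sse=sse)
    best = select_period(components, rel_sorted, config.period_window,
                         config.rel_err_ceiling)
    if best is not None:
        fit.selected_period = best.period
        fit.selected_phase = best.phase
        fit.selected_amplitude = best.amplitude
    return fit


def choose_leaf(left: RhythmFit, right: RhythmFit) -> RhythmFit | None:
    """Per-plant period rule: always the left leaf, the right only as fallback.

    Left and right leaves of one plant can disagree considerably, and
    averaging a reliable period with a noisy one degrades the estimate, so
    the left leaf's period is used whenever it exists; otherwise the right
    leaf's; if both are arrhythmic the plant is excluded (None).
    """
    if left.selected_period is not None:
        return left
    if right.selected_period is not None:
        return right
    return None
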