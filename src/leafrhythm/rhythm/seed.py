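"""Detrending and FFT seeding of the cosine model.

The growth drift of a seedling is removed first (default: ordinary
least-squares line; optionally a one-pass centred moving average).  A
zero-padded FFT of the detrended series then supplies starting values
(amplitude, period, phase) for the nonlinear fit: local power-spectrum maxima
inside the admissible period window, strongest first.
"""

from __future__ import annotations

import numpy as np

from ..errors import NoCandidateError
from ..series import TimeSeries
from .model import TWO_PI, CosineComponent

#: Zero-padding factor used to localise spectral peaks; the nonlinear fit
#: refines the period afterwards, so no taper window is applied.
PAD_FACTOR = 8

#: Local maxima below this fraction of the dominant spectral power are
#: side-lobe leakage ripple of the rectangular window, not candidates.
PEAK_POWER_FLOOR = 1e-3


def detrend_linear(series: TimeSeries) -> tuple[TimeSeries, tuple[float, float]]:
    """Subtract the OLS regression line fitted over non-missing samples.

    Returns the detrended series plus ``(slope, intercept)`` in px/h and px.
    The residuals have zero mean and zero linear trend by construction.
    """
    series.require_fittable()
    t, y = series.dropna()
    slope, intercept = np.polyfit(t, y, 1)
    resid = series.y - (slope * series.t + intercept)
    return series.replace(resid), (float(slope), float(intercept))


def detrend_moving_average(series: TimeSeries,
                           window_h: float = 24.0) -> tuple[TimeSeries, tuple[float, float]]:
    """Subtract a one-pass centred moving average (window in hours).

    Edge samples use the partial window.  The reported trend parameters are
    the OLS line of the subtracted baseline, for comparability with the
    linear mode.
    """
    series.require_fittable()
    t, y = series.t, series.y
    valid = series.valid
    baseline = np.full_like(y, np.nan)
    half = window_h / 2.0
    tv, yv = t[valid], y[valid]
    for i in np.nonzero(valid)[0]:
        m = np.abs(tv - t[i]) <= half
        baseline[i] = yv[m].mean()
    resid = y - baseline
    slope, intercept = np.polyfit(tv, baseline[valid], 1)
    return series.replace(resid), (float(slope), float(intercept))


def detrend(series: TimeSeries, mode: str = "linear",
            window_h: float = 24.0) -> tuple[TimeSeries, tuple[float, float]]:
    if mode == "linear":
        return detrend_linear(series)
    if mode == "moving-average":
        return detrend_moving_average(series, window_h)
    raise ValueError(f"unknown detrend mode {mode!r}")


def _interpolated(series: TimeSeries) -> np.ndarray:
    """Series values with missing samples linearly interpolated (FFT only)."""
    if series.n_valid == len(series.y):
        return series.y
    t, y = series.dropna()
    return np.interp(series.t, t, y)


def fft_seed(series: TimeSeries,
             period_window: tuple[float, float] | None,
             max_candidates: int = 4) -> list[CosineComponent]:
    """Spectral candidates for the cosine fit, strongest first.

    The mean-removed, linearly interpolated series is zero-padded to
    ``PAD_FACTOR`` times its length; local maxima of the power spectrum whose
    period falls inside ``period_window`` (or anywhere resolvable when the
    window is None) are converted to (A, T, phi) components.

    Raises
    ------
    NoCandidateError
        If no local spectral maximum falls inside the window.
    """
    series.require_fittable()
    y = _interpolated(series)
    y = y - y.mean()
    n = len(y)
    dt = float(np.mean(np.diff(series.t)))
    t0 = float(series.t[0])

    n_fft = int(2 ** np.ceil(np.log2(max(PAD_FACTOR * n, 16))))
    spectrum = np.fft.rfft(y, n_fft)
    freq = np.fft.rfftfreq(n_fft, d=dt)
    power = np.abs(spectrum) ** 2

    # local maxima, excluding DC and the last bin
    interior = np.arange(1, len(power) - 1)
    peaks = interior[(power[interior] > power[interior - 1])
                     & (power[interior] >= power[interior + 1])
                     & (power[interior] >= PEAK_POWER_FLOOR * power[1:].max())]
    periods = 1.0 / freq[peaks]
    if period_window is None:
        lo, hi = 2.0 * dt, 2.0 * (series.t[-1] - series.t[0])
    else:
        lo, hi = period_window
    keep = (periods >= lo) & (periods <= hi)
    peaks, periods = peaks[keep], periods[keep]
    if len(peaks) == 0:
        raise NoCandidateError(
            f"no spectral peak with period in [{lo:g}, {hi:g}] h")

    order = np.argsort(power[peaks])[::-1][:max_candidates]
    components = []
    for idx in order:
        k, period = peaks[idx], periods[idx]
        amplitude = 2.0 * np.abs(spectrum[k]) / n
        # X(w) ~ (n*A/2) * exp(-i*w*phi) for y = A*cos(w*(t - phi)), t from t0
        phase = (-np.angle(spectrum[k]) * period / TWO_PI + t0) % period
        components.append(CosineComponent(float(amplitude), float(period), float(phase)))
    return components
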