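"""Gauss-Newton nonlinear least squares for the sum-of-cosines model.

Plain Gauss-Newton diverges from poor seeds, so every step is safeguarded by
halving: the proposed step is shrunk (up to 20 times) until the residual sum
of squares decreases.  Convergence is declared when the relative SSE change
drops below 1e-8, when no shrunken step improves an already-stationary point,
or after 100 iterations.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConvergenceError
from .model import (CosineComponent, components_to_params, evaluate_params,
                    model_jacobian, n_cosine_terms, params_to_components)

MAX_ITER = 100
MAX_HALVINGS = 20
SSE_RTOL = 1e-8

#: Periods longer than this multiple of the observation span are not
#: identifiable (a cosine fraction degenerates into a trend surrogate with
#: runaway amplitude); the step safeguard keeps every period below it.
MAX_PERIOD_SPAN_FACTOR = 4.0


def sse_of_params(params: np.ndarray, t: np.ndarray, y: np.ndarray,
                  affine: bool = False) -> float:
    r = y - evaluate_params(params, t, affine)
    return float(r @ r)


def gn_minimize(t: np.ndarray, y: np.ndarray, params0: np.ndarray,
                free: np.ndarray | None = None,
                affine: bool = False) -> tuple[np.ndarray, float]:
    """Minimise the SSE over the internal [a, b, T]*K (+ affine) vector.

    Parameters marked False in ``free`` are held at their initial values
    (used by the support-plane search to pin one period); with ``affine``
    the trailing two entries are an intercept/slope correction fitted
    jointly.  Returns the optimised vector and its SSE.
    """
    params = np.array(params0, dtype=float)
    if free is None:
        free = np.ones(len(params), dtype=bool)
    free = np.asarray(free, dtype=bool)
    if not free.any():
        return params, sse_of_params(params, t, y, affine)

    span = float(t[-1] - t[0]) if len(t) > 1 else 1.0
    max_period = MAX_PERIOD_SPAN_FACTOR * span
    n_cos = n_cosine_terms(params, affine)
    period_free = np.zeros(len(params), dtype=bool)
    period_free[[3 * k + 2 for k in range(n_cos)]] = True
    period_free &= free
    sse = sse_of_params(params, t, y, affine)
    n_success = 0
    for _ in range(MAX_ITER):
        resid = y - evaluate_params(params, t, affine)
        jac = model_jacobian(params, t, free, affine)
        step, *_ = np.linalg.lstsq(jac, resid, rcond=None)

        # step halving: shrink until the SSE decreases; free periods are
        # projected into [min_period, max_period] rather than rejected, so a
        # runaway trend-surrogate term parks at the bound instead of killing
        # the whole step
        improved = False
        scale = 1.0
        min_period = 0.5 * span / max(len(t) - 1, 1)
        for _ in range(MAX_HALVINGS):
            trial = params.copy()
            trial[free] = params[free] + scale * step
            trial[period_free] = np.clip(trial[period_free], min_period, max_period)
            trial_sse = sse_of_params(trial, t, y, affine)
            if trial_sse < sse:
                improved = True
                break
            scale *= 0.5
        if not improved:
            # No downhill step found.  If the Gauss-Newton model predicts no
            # meaningful SSE decrease we are at a (possibly constrained)
            # stationary point; if we improved earlier we are at the numerical
            # floor.  Otherwise the seed is pathological.
            js = jac @ step
            predicted = 2.0 * (resid @ js) - js @ js
            if (n_success > 0 or sse <= 1e-300
                    or predicted <= SSE_RTOL * max(sse, 1e-300)):
                break
            raise ConvergenceError(
                "step halving exhausted without SSE decrease "
                f"(sse={sse:.3g}); the seed components are pathological"
            )
        n_success += 1
        params, prev_sse, sse = trial, sse, trial_sse
        if prev_sse - sse <= SSE_RTOL * max(prev_sse, 1e-300):
            break
    return params, sse


def gn_fit(t: np.ndarray, y: np.ndarray,
           seed_components: list[CosineComponent]) -> tuple[list[CosineComponent], float]:
    """Refine seed cosine components on a detrended series.

    Returns the optimised components in the (A, T, phi) convention together
    with the residual sum of squares.
    """
    if not seed_components:
        raise ValueError("at least one seed component is required")
    params0 = components_to_params(seed_components)
    params, sse = gn_minimize(np.asarray(t, float), np.asarray(y, float), params0)
    return params_to_components(params), sse
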