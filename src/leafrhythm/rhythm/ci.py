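"""Support-plane joint confidence intervals and relative errors.

For a least-squares fit with n samples and p free parameters, the
support-plane interval of one parameter theta_j is found by displacing it
from its estimate and re-optimising all remaining parameters until the
residual sum of squares reaches

    SSE_target = SSE_min * (1 + p/(n-p) * F(p, n-p; 1-alpha)).

The relative error of the parameter is the larger of the two displacement
half-widths divided by |theta_hat|; the rhythm pipeline computes it for every
fitted period and selects the component with the least relative error.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import optimize, stats

from ..errors import CIError, ConvergenceError
from .fit import gn_minimize

#: Displacement cap (as a fraction of |theta_hat|) beyond which a parameter
#: is declared unidentifiable.
MAX_DISPLACEMENT_FRAC = 0.5


def sse_target(sse_min: float, n: int, p: int, alpha: float) -> float:
    """F-scaled SSE threshold defining the joint confidence region."""
    if n <= p:
        raise ValueError("need more samples than free parameters")
    fcrit = stats.f.ppf(1.0 - alpha, p, n - p)
    return sse_min * (1.0 + p / (n - p) * fcrit)


def support_plane_halfwidth(refit_sse: Callable[[float], float],
                            theta_hat: float, sse_min: float,
                            n: int, p: int, alpha: float = 0.05,
                            max_frac: float = MAX_DISPLACEMENT_FRAC) -> float:
    """Half-width of the support-plane interval for one parameter.

    ``refit_sse(value)`` must return the SSE minimised over all other
    parameters with the parameter of interest fixed at ``value``.  Both
    displacement directions are searched by bracketing and bisection; the
    larger of the two is returned.

    Raises
    ------
    CIError
        If the SSE target is not reached within ``max_frac * |theta_hat|``
        displacement in either direction (parameter unidentifiable).
    """
    target = sse_target(sse_min, n, p, alpha)
    scale = abs(theta_hat)
    if scale == 0:
        scale = 1.0
    xtol = 1e-8 * scale
    widths = []
    for sign in (+1.0, -1.0):

        def excess(delta: float, _sign: float = sign) -> float:
            return refit_sse(theta_hat + _sign * delta) - target

        hi = 1e-8 * scale
        # expand until the target is bracketed
        while excess(hi) < 0.0:
            hi *= 2.0
            if hi > max_frac * scale:
                raise CIError(
                    f"SSE target not reached within {max_frac:.0%} displacement; "
                    "parameter unidentifiable")
        if hi <= xtol:
            widths.append(hi)  # essentially zero residuals: interval collapses
            continue
        lo = 0.0
        delta = optimize.brentq(excess, lo, hi, xtol=xtol)
        widths.append(delta)
    return float(max(widths))


def period_relative_errors(t: np.ndarray, y: np.ndarray,
                           params: np.ndarray, sse_min: float,
                           alpha: float = 0.05,
                           affine: bool = False) -> np.ndarray:
    """Support-plane relative error of each period in a fitted model.

    ``params`` is the internal [a, b, T]*K (optionally + [c0, c1]) vector at
    the optimum.  For each component the period is pinned at displaced
    values while every other parameter (all a, b, the remaining periods and
    any affine correction) is re-optimised by Gauss-Newton, warm-started
    from the optimum.  Components whose interval cannot be bracketed get
    relative error ``inf``.
    """
    n = len(t)
    p = len(params)
    n_comp = (p - 2 * affine) // 3
    rel_errs = np.empty(n_comp)
    for k in range(n_comp):
        j = 3 * k + 2
        free = np.ones(p, dtype=bool)
        free[j] = False
        theta_hat = params[j]

        def refit_sse(value: float, _j: int = j, _free: np.ndarray = free) -> float:
            trial = params.copy()
            trial[_j] = value
            _, sse = gn_minimize(t, y, trial, free=_free, affine=affine)
            return sse

        try:
            halfwidth = support_plane_halfwidth(
                refit_sse, theta_hat, sse_min, n, p, alpha)
            rel_errs[k] = halfwidth / abs(theta_hat)
        except (CIError, ConvergenceError):
            rel_errs[k] = np.inf
    return rel_errs
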