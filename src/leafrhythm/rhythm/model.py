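"""Sum-of-cosines rhythm model.

The fitted model is

    f(t) = sum_k A_k * cos(2*pi*(t - phi_k)/T_k)

with amplitude A_k (pixels), period T_k (hours) and phase phi_k (hours, time
of the first peak after t=0, in [0, T_k)).  Internally the fitter works in
the equivalent linear-in-(a, b) form

    a_k*cos(2*pi*t/T_k) + b_k*sin(2*pi*t/T_k)

which avoids phase wrap-around during optimisation; this module holds the
conversions between the two conventions and the model evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class CosineComponent:
    """One cosine term: amplitude (px), period (h), phase (h in [0, T))."""

    amplitude: float
    period: float
    phase: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.period <= 0:
            raise ValueError("period must be positive")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.cos(TWO_PI * (t - self.phase) / self.period)


def components_to_params(components: list[CosineComponent]) -> np.ndarray:
    """Pack (A, T, phi) components into the internal [a, b, T]*K vector."""
    params = np.empty(3 * len(components))
    for k, c in enumerate(components):
        delta = TWO_PI * c.phase / c.period
        params[3 * k] = c.amplitude * np.cos(delta)      # a
        params[3 * k + 1] = c.amplitude * np.sin(delta)  # b
        params[3 * k + 2] = c.period                     # T
    return params


def params_to_components(params: np.ndarray,
                         affine: bool = False) -> list[CosineComponent]:
    """Unpack the internal vector into (A, T, phi) components.

    phi is reduced to [0, T): a*cos(wt) + b*sin(wt) = A*cos(w*(t - phi)) with
    A = hypot(a, b) and w*phi = atan2(b, a).  A trailing affine pair, if
    present, is not a component and is skipped.
    """
    components = []
    for k in range(n_cosine_terms(params, affine)):
        a, b, period = params[3 * k: 3 * k + 3]
        amplitude = float(np.hypot(a, b))
        phase = float(np.arctan2(b, a) * period / TWO_PI) % period
        components.append(CosineComponent(amplitude, float(period), phase))
    return components


def n_cosine_terms(params: np.ndarray, affine: bool = False) -> int:
    return (len(params) - 2 * affine) // 3


def evaluate_params(params: np.ndarray, t: np.ndarray,
                    affine: bool = False) -> np.ndarray:
    """Evaluate the model for an internal [a, b, T]*K (+ [c0, c1]) vector.

    With ``affine`` set, the last two entries are an intercept and slope
    fitted jointly with the cosines; they absorb the small affine leakage
    that linear pre-detrending leaves behind (finite-window cosines are not
    exactly orthogonal to lines).
    """
    out = np.zeros_like(t, dtype=float)
    for k in range(n_cosine_terms(params, affine)):
        a, b, period = params[3 * k: 3 * k + 3]
        theta = TWO_PI * t / period
        out += a * np.cos(theta) + b * np.sin(theta)
    if affine:
        out += params[-2] + params[-1] * t
    return out


def evaluate_components(components: list[CosineComponent], t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    for c in components:
        out += c.evaluate(t)
    return out


def model_jacobian(params: np.ndarray, t: np.ndarray,
                   free: np.ndarray | None = None,
                   affine: bool = False) -> np.ndarray:
    """Jacobian of the model w.r.t. the internal parameters.

    Columns follow the packing order [a_1, b_1, T_1, a_2, ..., (c0, c1)];
    if ``free`` (boolean mask) is given, only those columns are returned.
    """
    n_par = len(params)
    jac = np.empty((len(t), n_par))
    if affine:
        jac[:, -2] = 1.0
        jac[:, -1] = t
    for k in range(n_cosine_terms(params, affine)):
        a, b, period = params[3 * k: 3 * k + 3]
        theta = TWO_PI * t / period
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        jac[:, 3 * k] = cos_t
        jac[:, 3 * k + 1] = sin_t
        # d/dT [a cos(wt) + b sin(wt)], w = 2*pi/T:
        # (-a sin + b cos) * t * dw/dT = (a sin - b cos) * 2*pi*t/T^2
        jac[:, 3 * k + 2] = (a * sin_t - b * cos_t) * TWO_PI * t / period ** 2
    if free is not None:
        jac = jac[:, free]
    return jac
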