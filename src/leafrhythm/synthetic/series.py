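"""Simulated leaf-movement time series.

The study conditions for validating the period estimator: a cosine of
circadian period with additive uniform noise scaled to the amplitude
(15% -> noise drawn from U(-0.15*A, +0.15*A)), an optional linear growth
trend, an optional phase delay; sampled every 10 minutes over 120 h (five
cycles) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..errors import SpecError
from ..series import TimeSeries


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic tip-position series.

    noise_frac is the half-width of the uniform noise as a fraction of the
    cosine amplitude; values above 1 are still fractions (2.0 -> +/-2A).
    """

    period_h: float
    amplitude: float = 10.0       # px
    phase_h: float = 0.0          # time of first peak, h
    trend_slope: float = 0.0      # px/h
    noise_frac: float = 0.15
    duration_h: float = 120.0
    interval_min: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.period_h <= 0:
            raise SpecError("period_h must be positive")
        if self.noise_frac < 0:
            raise SpecError("noise_frac must be non-negative")
        if self.amplitude < 0:
            raise SpecError("amplitude must be non-negative")
        if self.interval_min <= 0:
            raise SpecError("interval_min must be positive")
        if self.duration_h < 2 * self.period_h:
            raise SpecError("duration_h must cover at least two periods")


def simulate_series(spec: SimulationSpec,
                    label: str = "sim") -> tuple[TimeSeries, dict]:
    """Generate y(t) = A*cos(2*pi*(t - phi)/T) + m*t + U(-eta*A, eta*A).

    Deterministic given ``spec.seed``.  Returns the series and the ground
    truth dict (period_h, phase_h, amplitude, trend_slope) for recovery
    tests.
    """
    spec.validate()
    dt = spec.interval_min / 60.0
    n = int(round(spec.duration_h / dt)) + 1
    t = np.arange(n) * dt
    clean = spec.amplitude * np.cos(2.0 * np.pi * (t - spec.phase_h) / spec.period_h)
    rng = np.random.default_rng(spec.seed)
    eta = spec.noise_frac * spec.amplitude
    noise = rng.uniform(-eta, eta, size=n) if eta > 0 else np.zeros(n)
    y = clean + spec.trend_slope * t + noise
    truth = {"period_h": spec.period_h, "phase_h": spec.phase_h,
             "amplitude": spec.amplitude, "trend_slope": spec.trend_slope}
    return TimeSeries(t, y, label), truth


def derived_seed(base_seed: int, *keys: int) -> int:
    """Stable sub-stream seed below 2**31 for (base, keys)."""
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def noise_titration(base: SimulationSpec,
                    fractions: list[float]) -> list[tuple[TimeSeries, dict]]:
    """One simulated series per noise fraction, with per-fraction seeds.

    Fraction 0 reproduces the noiseless base exactly; other fractions use
    seeds derived deterministically from the base seed and the fraction
    index.
    """
    out = []
    for i, frac in enumerate(fractions):
        if frac < 0:
            raise SpecError("noise fractions must be non-negative")
        spec = replace(base, noise_frac=float(frac),
                       seed=base.seed if frac == 0 else derived_seed(base.seed, i))
        out.append(simulate_series(spec, label=f"noise{frac:g}"))
    return out
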