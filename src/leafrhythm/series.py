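"""Uniformly sampled leaf-tip position series.

The fundamental container shared by the imaging, synthetic and rhythm layers:
sample times in hours plus the tip's vertical position in pixels, with NaN
marking frames where detection failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError

#: Minimum number of non-missing samples required before a rhythm fit is
#: attempted (8 h of data at the default 10-min sampling interval).
MIN_SAMPLES = 48


@dataclass
class TimeSeries:
    """One leaf's vertical tip position over time.

    Parameters
    ----------
    t : array of float
        Sample times in hours, strictly increasing.
    y : array of float
        Tip position in pixels; NaN encodes a missing frame.
    label : str
        Free-text identifier (typically ``c<chamber>_<left|right>``).
    """

    t: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-missing samples."""
        return ~np.isnan(self.y)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def dropna(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (t, y) restricted to non-missing samples."""
        m = self.valid
        return self.t[m], self.y[m]

    def require_fittable(self, min_samples: int = MIN_SAMPLES) -> None:
        """Raise :class:`InsufficientDataError` if too short to fit."""
        if self.n_valid < min_samples:
            raise InsufficientDataError(
                f"series {self.label!r} has {self.n_valid} usable samples; "
                f"at least {min_samples} are required"
            )

    def replace(self, y: np.ndarray, label: str | None = None) -> "TimeSeries":
        """Copy with new values on the same time grid."""
        return TimeSeries(self.t.copy(), np.asarray(y, dtype=float),
                          self.label if label is None else label)
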