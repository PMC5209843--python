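"""Run configuration with documented defaults.

One flat dataclass covers plate geometry, segmentation, rhythm analysis and
run metadata so that a single JSON file reproduces a run exactly.  Precedence
is CLI flag > config file > default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class Config:
    # --- plate geometry ---
    rows: int = 5                    # chamber grid rows
    cols: int = 5                    # chamber grid columns
    band: int = 4                    # tip-tracing border band in mask pixels (3-5)
    scale: float = 0.7               # working / full linear resolution for segmentation

    # --- red-mark (fiducial) detection ---
    hue_tol_deg: float = 15.0        # admissible angular deviation from red (hue 0)
    sat_min: float = 0.4             # saturation floor for mark pixels
    val_min: float = 0.3             # value floor for mark pixels
    min_mark_area_frac: float = 0.005  # blobs below this fraction of the image are noise
    layout_slack: float = 0.10       # tiled grid may exceed the plate span by this much

    # --- segmentation / metric blob filter ---
    contrast_iterations: int = 8     # luminance shearing passes before binarisation
    contrast_gain: float = 0.10      # extra linear stretch about mid-grey per pass
    w_dist: float = 0.5              # metric-filter weight: centroid distance to centre
    w_area: float = 0.3              # metric-filter weight: blob area deficit
    w_form: float = 0.2              # metric-filter weight: elongation penalty
    blob_accept: float = 0.35        # plant-likeness score needed to join the union
    merge_radius_frac: float = 0.5   # merge radius as a fraction of the chamber diagonal
    mask_red_fiducials: bool = True  # white out registration-mark pixels before contrasting
    detect_floor: float = 0.8        # minimum per-chamber detection rate for a usable trace

    # --- rhythm analysis ---
    period_window: tuple[float, float] = (15.0, 35.0)  # admissible circadian periods, h
    detrend: str = "linear"          # "linear" (regression) or "moving-average"
    ma_window_h: float = 24.0        # moving-average window when detrend="moving-average"
    alpha: float = 0.05              # support-plane confidence level
    term_var_threshold: float = 0.1  # minimum residual-variance fraction a new term must explain
    rel_err_ceiling: float = 0.15    # periods with larger relative error are unreliable
    max_terms: int = 4               # cosine terms in the fitting function

    # --- run metadata ---
    interval_min: float = 10.0       # sampling interval of the image stack, minutes
    seed: int = 0

    def __post_init__(self) -> None:
        self.period_window = tuple(float(v) for v in self.period_window)  # type: ignore[assignment]
        if not 3 <= self.band <= 5:
            raise ValueError("band must be in 3..5")
        if self.detrend not in ("linear", "moving-average"):
            raise ValueError("detrend must be 'linear' or 'moving-average'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period_window"] = list(self.period_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Config":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def updated(self, **kwargs) -> "Config":
        """Copy with the given fields replaced (None values are ignored)."""
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **clean)
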