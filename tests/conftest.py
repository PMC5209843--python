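"""Shared fixtures: a small rendered plate stack and simulation helpers.

All fixtures are generated programmatically at test time; nothing is stored
on disk beyond pytest's tmp directories.
"""

from __future__ import annotations

import numpy as np
import pytest

from leafrhythm import Config, PlateRenderSpec, SimulationSpec
from leafrhythm.synthetic import render_plate_series


@pytest.fixture(scope="session")
def short_plate(tmp_path_factory):
    """An 8-frame rendered plate with one empty chamber and edge clutter."""
    spec = PlateRenderSpec(n_frames=8, seed=11, empty_chambers=(7,),
                           speckle_density=0.5)
    out = tmp_path_factory.mktemp("plate8")
    paths, truth = render_plate_series(spec, out)
    return spec, paths, truth


@pytest.fixture()
def config():
    return Config()


def make_series(period_h=24.0, seed=0, **kwargs):
    """Convenience wrapper used across rhythm tests."""
    from leafrhythm.synthetic import simulate_series
    spec = SimulationSpec(period_h=period_h, seed=seed, **kwargs)
    return simulate_series(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
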