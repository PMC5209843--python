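"""Synthetic series generator and plate renderer."""

import numpy as np
import pytest

from leafrhythm import SimulationSpec, SpecError
from leafrhythm.synthetic import (PlateRenderSpec, noise_titration,
                                  render_plate_series, simulate_series)


class TestSimulateSeries:
    def test_noiseless_cosine_values(self):
        series, truth = simulate_series(
            SimulationSpec(period_h=24, amplitude=10, noise_frac=0))
        # t = 0 is a peak, t = 12 h a trough, exactly
        assert series.y[0] == pytest.approx(10.0, abs=1e-12)
        i12 = int(round(12 / (series.t[1] - series.t[0])))
        assert series.t[i12] == pytest.approx(12.0)
        assert series.y[i12] == pytest.approx(-10.0, abs=1e-12)

    def test_grid_is_ten_minute_sampling_over_120h(self):
        series, _ = simulate_series(SimulationSpec(period_h=24))
        assert len(series.t) == 721
        assert np.allclose(np.diff(series.t), 1 / 6)

    def test_seed_changes_noise_not_truth(self):
        s1, t1 = simulate_series(SimulationSpec(period_h=24, seed=1))
        s2, t2 = simulate_series(SimulationSpec(period_h=24, seed=2))
        assert t1 == t2
        assert not np.array_equal(s1.y, s2.y)
        s1b, _ = simulate_series(SimulationSpec(period_h=24, seed=1))
        assert np.array_equal(s1.y, s1b.y)

    def test_uniform_noise_moments(self):
        # noise at 200% of A=10: bounded by +/-20, SD ~ 2A/sqrt(3)
        spec = SimulationSpec(period_h=24, noise_frac=2.0, duration_h=2000,
                              seed=7)
        series, _ = simulate_series(spec)
        clean, _ = simulate_series(
            SimulationSpec(period_h=24, noise_frac=0, duration_h=2000))
        eps = series.y - clean.y
        assert len(eps) >= 10_000
        assert np.abs(eps).max() <= 20.0
        expected_sd = 20.0 / np.sqrt(3)
        assert np.std(eps) == pytest.approx(expected_sd, rel=0.10)
        # zero mean within 3 standard errors
        assert abs(eps.mean()) <= 3 * expected_sd / np.sqrt(len(eps))

    @pytest.mark.parametrize("bad", [
        dict(period_h=-1), dict(period_h=24, noise_frac=-0.1),
        dict(period_h=24, duration_h=30), dict(period_h=24, interval_min=0),
    ])
    def test_invalid_spec_raises(self, bad):
        with pytest.raises(SpecError):
            simulate_series(SimulationSpec(**bad))


class TestNoiseTitration:
    def test_series_lengths_and_count(self):
        base = SimulationSpec(period_h=24, seed=3)
        out = noise_titration(base, [0.2, 0.4, 0.6, 0.8, 1.0, 2.0])
        assert len(out) == 6
        assert len({len(s.y) for s, _ in out}) == 1

    def test_zero_fraction_reproduces_noiseless_base(self):
        base = SimulationSpec(period_h=24, seed=3)
        (series, _), = noise_titration(base, [0.0])
        clean, _ = simulate_series(
            SimulationSpec(period_h=24, noise_frac=0, seed=3))
        assert np.array_equal(series.y, clean.y)

    def test_deterministic_per_fraction(self):
        base = SimulationSpec(period_h=24, seed=3)
        a = noise_titration(base, [0.5, 1.0])
        b = noise_titration(base, [0.5, 1.0])
        for (sa, _), (sb, _) in zip(a, b):
            assert np.array_equal(sa.y, sb.y)


class TestPlateRenderer:
    def test_static_scene_is_byte_identical_across_frames(self, tmp_path):
        spec = PlateRenderSpec(n_frames=2, seed=5,
                               motion=SimulationSpec(period_h=24, amplitude=0,
                                                     noise_frac=0,
                                                     duration_h=120))
        paths, _ = render_plate_series(spec, tmp_path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_rerender_is_byte_identical(self, tmp_path):
        spec = PlateRenderSpec(n_frames=3, seed=5, speckle_density=1.0)
        p1, _ = render_plate_series(spec, tmp_path / "a")
        p2, _ = render_plate_series(spec, tmp_path / "b")
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_ground_truth_tip_rows_follow_driving_cosine(self, tmp_path):
        motion = SimulationSpec(period_h=24, amplitude=10, noise_frac=0,
                                duration_h=120)
        spec = PlateRenderSpec(n_frames=12, seed=5, motion=motion)
        _, truth = render_plate_series(spec, tmp_path)
        expected = 10 * np.cos(2 * np.pi * truth.times_h / 24)
        for idx in truth.planted:
            assert np.allclose(truth.motion[idx], expected)
            # upward displacement decreases the image row
            base = truth.tip_rows[idx] + truth.motion[idx]
            assert np.allclose(base, base[0])

    def test_grid_must_fit_image(self, tmp_path):
        with pytest.raises(SpecError):
            render_plate_series(
                PlateRenderSpec(width=300, height=300, chamber_size=100),
                tmp_path)
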