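"""Acquisition patterns, tilt calibration, and the hologram simulator."""

import math

import numpy as np
import pytest

from uvholo.config import PipelineConfig
from uvholo.pipeline import preprocess_stack
from uvholo.simulate import (
    CIRCULAR,
    RECTANGULAR,
    HologramSimulator,
    NoiseScene,
    ParasiticPlane,
    Scatterer,
    SensorModel,
    UnsupportedSceneError,
    calibrate_shift_map,
    make_pattern,
    simulate_frame,
    simulate_stack,
    tilt_for_shift,
)
from uvholo.superres import FrameStack, estimate_shifts

Z2 = 400.0


class TestMakePattern:
    def test_platform_pattern_counts(self):
        p = make_pattern(14, 0.16, 12, 0.3, 30)
        assert len(p) == 556
        assert p.n_rectangular == 196
        assert p.n_circular == 360

    def test_single_entry(self):
        p = make_pattern(1, 0.16, 0, 0.3, 0)
        assert len(p) == 1
        np.testing.assert_allclose(p.shifts, [[0.0, 0.0]])

    def test_circle_geometry(self):
        p = make_pattern(2, 0.16, 1, 0.3, 4)
        assert len(p) == 8
        circ = p.shifts[p.kinds == CIRCULAR]
        expected = [(0.3, 0.0), (0.0, 0.3), (-0.3, 0.0), (0.0, -0.3)]
        np.testing.assert_allclose(circ, expected, atol=1e-12)
        rect = p.shifts[p.kinds == RECTANGULAR]
        np.testing.assert_allclose(np.abs(rect), 0.08, atol=1e-12)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            make_pattern(-1, 0.16, 0, 0.3, 0)


class TestTiltCalibration:
    def test_zero_shift_zero_tilt(self):
        assert tilt_for_shift((0.0, 0.0), Z2) == (0.0, 0.0)

    def test_small_angle_formula(self):
        tx, ty = tilt_for_shift((0.16, 0.0), 500.0)
        assert tx == pytest.approx(math.degrees(math.atan(0.16 / 500.0)))
        assert tx == pytest.approx(0.0183, abs=1e-4)
        assert ty == 0.0

    def test_rejects_nonpositive_height(self):
        with pytest.raises(ValueError):
            tilt_for_shift((0.1, 0.0), 0.0)

    def test_exact_linear_fit(self):
        t = np.array([0.05, 0.1, 0.2])
        cal = calibrate_shift_map(t, 8.7 * t)
        assert cal.slope[0] == pytest.approx(8.7, rel=1e-12)

    def test_noisy_fit_within_2_percent(self, rng):
        t = np.array([0.05, 0.1, 0.2])
        s = 8.7 * t * (1 + 0.01 * rng.standard_normal(3))
        cal = calibrate_shift_map(t, s)
        assert cal.slope[0] == pytest.approx(8.7, rel=0.02)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            calibrate_shift_map([0.1], [0.87])

    def test_round_trip_against_registration(self, dust_simulator):
        """Tilting by tilt_for_shift((0.32, 0)) moves the hologram by
        0.32 um, recovered by cross-correlation to within 0.02 um."""
        f0 = dust_simulator.frame((0.0, 0.0))
        f1 = dust_simulator.frame(tilt_for_shift((0.32, 0.0), Z2))
        st = FrameStack(
            np.stack([f0, f1]).astype(float), np.zeros((2, 2)), pitch=1.12
        )
        est = estimate_shifts(st)
        assert est[1, 0] == pytest.approx(0.32, abs=0.02)
        assert est[1, 1] == pytest.approx(0.0, abs=0.02)


class TestSimulateFrame:
    def test_empty_scene_uniform(self):
        f = simulate_frame(
            [], (0.0, 0.0), SensorModel.noiseless(bayer="mono"),
            NoiseScene.quiet(), shape=(64, 64),
        )
        assert f.min() == f.max()

    def test_centered_particle_hologram_symmetric(self):
        # particle at the fine-grid symmetry centre -> mirror-symmetric
        # concentric fringes; radial asymmetry below 1% of the mean
        n, sub = 128, 4
        c = (n * sub - 1) / 2 * (1.12 / sub)
        sim = HologramSimulator(
            [Scatterer(x=c, y=c, z2=Z2, diameter=250, strength=0.6 - 0.5j)],
            SensorModel.noiseless(bayer="mono"), NoiseScene.quiet(), shape=(n, n),
        )
        inten = sim.sensor_intensity((0.0, 0.0))
        assert np.abs(inten - inten[:, ::-1]).max() / inten.mean() < 1e-5
        assert np.abs(inten - inten[::-1, :]).max() / inten.mean() < 1e-5
        cpix = ((n * sub - 1) / 2 - 1.5) / sub
        yy, xx = np.mgrid[0:n, 0:n]
        rb = np.round(np.hypot(yy - cpix, xx - cpix)).astype(int)
        counts = np.maximum(np.bincount(rb.ravel()), 1)
        prof = np.bincount(rb.ravel(), inten.ravel()) / counts
        m = rb < 30
        asym = np.sqrt(np.mean((inten[m] - prof[rb][m]) ** 2)) / inten.mean()
        assert asym < 0.01

    def test_integer_pixel_shift(self, quiet_simulator):
        f0 = quiet_simulator.frame((0.0, 0.0)).astype(float)
        f1 = quiet_simulator.frame(tilt_for_shift((1.12, 0.0), Z2)).astype(float)
        diff = f1[:, 1:] - f0[:, :-1]
        assert np.sqrt(np.mean(diff**2)) / f0.mean() < 0.005

    def test_mixed_heights_rejected(self):
        scene = [
            Scatterer(x=10, y=10, z2=400.0),
            Scatterer(x=20, y=20, z2=410.0),
        ]
        with pytest.raises(UnsupportedSceneError):
            simulate_frame(scene, shape=(64, 64))

    def test_seed_required_with_noise(self):
        with pytest.raises(ValueError):
            simulate_frame([], sensor=SensorModel(), noise=NoiseScene.quiet(),
                           shape=(64, 64), seed=None)

    def test_determinism(self):
        kw = dict(
            scene=[Scatterer(x=30, y=30, z2=Z2, diameter=300)],
            tilt_deg=(0.01, -0.01), sensor=SensorModel(), noise=NoiseScene(),
            seed=99, shape=(64, 64),
        )
        np.testing.assert_array_equal(simulate_frame(**kw), simulate_frame(**kw))


class TestSimulatorPhysics:
    def test_hologram_shift_linear_in_tan_tilt(self, dust_simulator):
        """Measured hologram displacement vs tan(theta) has slope z2
        within 2% for tilts up to 0.5 degrees."""
        tilts = [0.1, 0.25, 0.5]
        frames = [dust_simulator.frame((0.0, 0.0))]
        for t in tilts:
            frames.append(dust_simulator.frame((t, 0.0)))
        st = FrameStack(
            np.stack(frames).astype(float),
            np.zeros((len(frames), 2)), pitch=1.12,
        )
        est = estimate_shifts(st)
        tans = np.tan(np.radians(tilts))
        slope = np.sum(est[1:, 0] * tans) / np.sum(tans**2)
        assert slope == pytest.approx(Z2, rel=0.02)

    def test_nanolens_gain_scales_modulation(self):
        """Fringe modulation depth of a weak scatterer is linear in the
        nanolens gain (+-5%) with the background level unchanged."""
        def depth(g):
            c = 71.68
            sim = HologramSimulator(
                [Scatterer(x=c, y=c, z2=Z2, diameter=80,
                           strength=0.1 - 0.08j, nanolens_gain=g)],
                SensorModel.noiseless(bayer="mono"), NoiseScene.quiet(),
                shape=(128, 128),
            )
            inten = sim.sensor_intensity((0.0, 0.0))
            return np.abs(inten - inten[0, 0]).max() / inten[0, 0], inten[0, 0]

        d1, b1 = depth(1.0)
        d2, b2 = depth(2.0)
        d4, b4 = depth(4.0)
        assert d2 / d1 == pytest.approx(2.0, rel=0.05)
        assert d4 / d1 == pytest.approx(4.0, rel=0.05)
        assert b2 == pytest.approx(b1, rel=1e-3)
        assert b4 == pytest.approx(b1, rel=1e-3)

    def test_parasitic_plane_moves_differently(self):
        """Structure from an out-of-sample plane shifts by h*tan(theta),
        not z2*tan(theta)."""
        from uvholo.simulate import SpeckleModel

        noise = NoiseScene(
            parasitic_planes=[],
            speckle=SpeckleModel(height=1000.0, contrast=0.2, correlation_length=5.0),
        )
        sim = HologramSimulator([], SensorModel.noiseless(bayer="mono"),
                                noise, shape=(128, 128), z2=Z2)
        f0 = sim.sensor_intensity((0.0, 0.0))
        tilt = tilt_for_shift((1.12, 0.0), Z2)  # 1 px at the sample plane
        f1 = sim.sensor_intensity(tilt)
        st = FrameStack(np.stack([f0, f1]), np.zeros((2, 2)), pitch=1.12)
        est = estimate_shifts(st, window=(slice(None), slice(None)), apodize=0)
        # plane at 1000 um moves 2.5x the sample-plane displacement
        assert est[1, 0] == pytest.approx(1.12 * 1000.0 / Z2, abs=0.05)

    def test_stack_determinism_and_metadata(self):
        scene = [Scatterer(x=30, y=30, z2=Z2, diameter=300)]
        pat = make_pattern(2, 0.16, 1, 0.3, 4)
        s1 = simulate_stack(scene, pat, SensorModel(), NoiseScene(), seed=5, shape=(64, 64))
        s2 = simulate_stack(scene, pat, SensorModel(), NoiseScene(), seed=5, shape=(64, 64))
        np.testing.assert_array_equal(s1.frames, s2.frames)
        assert len(s1) == 8
        np.testing.assert_allclose(s1.nominal_shifts, pat.shifts)
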