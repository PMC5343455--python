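"""Background-compensated detection, focus curves, candidate criteria."""

import numpy as np
import pytest

from uvholo.detect import (
    CompensatedPhaseStack,
    FocusCurve,
    average_stack,
    classify_candidate,
    compensate_phase,
    contrast,
    find_candidates,
    focus_curve,
)
from uvholo.fields import lowpass
from uvholo.superres import HighResHologram

from conftest import CENTER, Z2

HR = 0.28


class TestCompensatePhase:
    def test_smooth_hologram_compensates_to_one(self, rng):
        smooth = lowpass(5 + rng.random((128, 128)), 0.01, pitch=HR)
        holo = HighResHologram(smooth, pitch=HR)
        comp = compensate_phase(holo, [300.0], cutoff=0.1)[0]
        assert np.abs(comp - 1).max() < 1e-6

    def test_offset_keeps_denominator_positive(self):
        # wrapped phase lives in (-pi, pi]; adding 2*pi bounds the
        # denominator below by +pi
        assert (-np.pi + 2 * np.pi) > 0
        phases = np.array([-np.pi + 1e-9, 0.0, np.pi])
        assert np.all(phases + 2 * np.pi >= np.pi)

    def test_background_flat_particle_prominent(self, noisy_particle_sr):
        sr, true_xy = noisy_particle_sr
        comp = compensate_phase(sr, [Z2], cutoff=0.1)[0]
        hy, hx = int(true_xy[1] / HR), int(true_xy[0] / HR)
        yy, xx = np.mgrid[0 : comp.shape[0], 0 : comp.shape[1]]
        r = np.hypot(yy - hy, xx - hx)
        bg = (r > 100) & (r < 200)
        bg_dev = np.abs(comp[bg] - 1).max()
        assert bg_dev < 0.02
        peak_dev = np.abs(comp[r < 10] - 1).max()
        assert peak_dev > 5 * bg_dev

    def test_empty_z_list_rejected(self, noisy_particle_sr):
        with pytest.raises(ValueError):
            compensate_phase(noisy_particle_sr[0], [])


class TestAverageStack:
    def test_identical_planes_unchanged(self, rng):
        img = rng.random((32, 32))
        np.testing.assert_allclose(average_stack(np.stack([img] * 5)), img)

    def test_two_plane_complement(self):
        a = np.zeros((4, 4))
        b = np.full((4, 4), 2.0)
        np.testing.assert_allclose(average_stack(np.stack([a + 2, b - 2])), 1.0)

    def test_noise_attenuates_as_sqrt_n(self, rng):
        base = np.zeros((64, 64))
        base[32, 32] = 1.0
        planes = np.stack([base + 0.2 * rng.standard_normal((64, 64)) for _ in range(41)])
        avg = average_stack(planes)
        reduction = planes[0][base == 0].std() / avg[base == 0].std()
        assert reduction >= 5.0  # 1/sqrt(41) ~ 6.4
        assert avg[32, 32] == pytest.approx(1.0, abs=0.2)

    def test_needs_two_planes(self):
        with pytest.raises(ValueError):
            average_stack(np.ones((1, 8, 8)))


class TestFindCandidates:
    def test_constant_image_empty(self):
        assert find_candidates(np.ones((50, 50)), k_sigma=6) == []

    def test_three_peaks_localised(self, rng):
        img = 1 + 0.001 * rng.standard_normal((200, 200))
        truth = [(50, 60), (120, 30), (160, 170)]
        for py, px in truth:
            yy, xx = np.mgrid[py - 3 : py + 4, px - 3 : px + 4]
            img[py - 3 : py + 4, px - 3 : px + 4] += 0.05 * np.exp(
                -((yy - py) ** 2 + (xx - px) ** 2) / 2.0
            )
        cands = find_candidates(img, k_sigma=6)
        assert len(cands) == 3
        for py, px in truth:
            d = min(np.hypot(cx - px, cy - py) for cx, cy, _ in cands)
            assert d < 1.0

    def test_threshold_is_strict(self):
        img = np.zeros((20, 20))
        img[::2, ::2] = 1.0  # bimodal -> MAD-based sigma positive
        med = np.median(img)
        sigma = 1.4826 * np.median(np.abs(img - med))
        thr = med + 2.0 * sigma
        img2 = np.full((20, 20), med)
        img2[5:7, 5] = thr  # exactly at threshold
        assert find_candidates(img2, k_sigma=2.0) == []

    def test_monotone_in_k_sigma(self, rng):
        img = rng.standard_normal((128, 128))
        counts = [len(find_candidates(img, k_sigma=k)) for k in (1.0, 2.0, 3.0, 4.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_rejects_bad_k(self):
        with pytest.raises(ValueError):
            find_candidates(np.ones((8, 8)), k_sigma=0)


class TestFocusCurve:
    def test_default_sampling_has_41_points(self, noisy_particle_sr):
        sr, true_xy = noisy_particle_sr
        c = focus_curve(sr, true_xy[0] / HR, true_xy[1] / HR, Z2)
        assert len(c.z_values) == 41
        assert np.allclose(np.diff(c.z_values), 2.0)

    def test_particle_curve_peaks_near_true_height(self, noisy_particle_sr):
        sr, true_xy = noisy_particle_sr
        c = focus_curve(sr, true_xy[0] / HR, true_xy[1] / HR, Z2)
        z_pk = c.z_values[np.argmax(c.peak_phase)]
        assert abs(z_pk - Z2) <= 4.0

    def test_noise_location_less_peaked_than_particle(self, noisy_particle_sr):
        sr, true_xy = noisy_particle_sr
        stack = CompensatedPhaseStack(sr, cutoff=0.1)
        cp = focus_curve(stack, true_xy[0] / HR, true_xy[1] / HR, Z2)
        ratio_particle = cp.peak_phase.max() / np.median(cp.peak_phase)
        # empty corner of the field: no consistent focus
        cn = focus_curve(stack, 80, 80, Z2, window_radius=5)
        ratio_noise = cn.peak_phase.max() / np.median(cn.peak_phase)
        assert ratio_particle > ratio_noise

    def test_window_outside_grid_rejected(self, noisy_particle_sr):
        sr, _ = noisy_particle_sr
        with pytest.raises(ValueError):
            focus_curve(sr, 2, 2, Z2, window_radius=5)

    def test_nonuniform_z_rejected(self):
        with pytest.raises(ValueError):
            FocusCurve(np.array([0.0, 1.0, 3.0]), np.zeros(3))


class TestClassifyCandidate:
    Z0 = 400.0
    ZS = np.arange(360.0, 441.0, 2.0)

    def test_strong_parabola_passes(self):
        fit = classify_candidate(FocusCurve(self.ZS, -1e-5 * (self.ZS - self.Z0) ** 2 + 1.2), self.Z0)
        assert fit.passed
        assert fit.a == pytest.approx(-1e-5, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.z_peak == pytest.approx(self.Z0, abs=1e-6)

    def test_shallow_parabola_fails_only_curvature(self):
        fit = classify_candidate(FocusCurve(self.ZS, -5e-6 * (self.ZS - self.Z0) ** 2 + 1.2), self.Z0)
        assert not fit.passed
        assert fit.reasons == ["quadratic_coefficient"]

    def test_flat_curve_fails_all_three(self):
        fit = classify_candidate(FocusCurve(self.ZS, np.full_like(self.ZS, 1.0)), self.Z0)
        assert not fit.passed
        assert set(fit.reasons) == {"quadratic_coefficient", "r_squared", "peak_location"}
        assert fit.r_squared == 0.0

    def test_invariant_to_constant_offset(self):
        y = -1e-5 * (self.ZS - self.Z0) ** 2 + 1.2
        f1 = classify_candidate(FocusCurve(self.ZS, y), self.Z0)
        f2 = classify_candidate(FocusCurve(self.ZS, y + 7.5), self.Z0)
        assert f1.a == pytest.approx(f2.a)
        assert f1.r_squared == pytest.approx(f2.r_squared)
        assert f1.z_peak == pytest.approx(f2.z_peak)

    def test_displaced_peak_fails_location(self):
        y = -2e-5 * (self.ZS - (self.Z0 + 20)) ** 2 + 1.2
        fit = classify_candidate(FocusCurve(self.ZS, y), self.Z0)
        assert "peak_location" in fit.reasons


class TestContrast:
    def test_formula_cases(self):
        img = np.ones((10, 10))
        tr = np.zeros((10, 10), bool)
        tr[4:6, 4:6] = True
        br = ~tr
        assert contrast(img, tr, br) == 0.0
        img[5, 5] = 0.0
        assert contrast(img, tr, br) == pytest.approx(1.0)
        img[5, 5] = 0.4
        assert contrast(img, tr, br) == pytest.approx(0.6)

    def test_negative_clipped_with_warning(self):
        img = np.ones((10, 10))
        img[5, 5] = 2.0  # brighter than background
        tr = np.zeros((10, 10), bool)
        tr[5, 5] = True
        img[tr] = 2.0
        with pytest.warns(UserWarning):
            assert contrast(img, tr, ~tr) == 0.0

    def test_region_validation(self):
        img = np.ones((10, 10))
        empty = np.zeros((10, 10), bool)
        with pytest.raises(ValueError):
            contrast(img, empty, ~empty)
        full = np.ones((10, 10), bool)
        with pytest.raises(ValueError):
            contrast(img, full, full)


@pytest.fixture(scope="module")
def noisy_particle_sr():
    """SR hologram of one bead over a structured coherent background."""
    from uvholo.config import PipelineConfig
    from uvholo.pipeline import preprocess_stack
    from uvholo.simulate import (
        NoiseScene, ParasiticPlane, Scatterer, SensorModel,
        make_pattern, simulate_stack,
    )
    from uvholo.superres import shift_and_add

    scene = [
        Scatterer(x=CENTER, y=CENTER, z2=Z2, diameter=300,
                  strength=0.5 - 0.4j, nanolens_gain=6.0)
    ]
    noise = NoiseScene(
        parasitic_planes=[ParasiticPlane(1500.0, 0.03, 30.0, 0.04)], speckle=None
    )
    pat = make_pattern(4, 0.28, 0, 0, 0)
    stack = simulate_stack(
        scene, pat, SensorModel.noiseless(bayer="mono"), noise, seed=1, shape=(128, 128)
    )
    pre = preprocess_stack(stack, PipelineConfig(), bayer=False)
    return shift_and_add(pre, factor=4), (CENTER, CENTER)
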