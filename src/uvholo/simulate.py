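"""Synthetic hologram acquisition for the UV on-chip platform.

Emulates the computational consequences of the instrument: a coherent
266 nm beam illuminates a sample plane a few hundred micrometres above a
1.12 um-pitch Bayer CMOS sensor; tilting the beam by an angle ``theta``
displaces the in-line hologram of the sample by ``z2 * tan(theta)``,
while coherent parasitic light (reflections, speckle) originating at
other heights ``h`` displaces by ``h * tan(theta)`` — the differential
motion the circular-averaging super-resolution step exploits.

A frame is synthesized on a grid ``subsample``x finer than the sensor
pitch, so that sub-pixel objects and shifts are explicit, then
integrated over the pixel aperture, Bayer-masked, and digitized with
gain, shot and read noise.

The tilt is applied as the equivalent paraxial lateral shift of each
optical plane's (precomputed) sensor field — exact to first order in the
tilt angle, which never exceeds ~0.5 degrees here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.fft as sfft

from .fields import ComplexField, propagate
from .superres import FrameStack

__all__ = [
    "Scatterer",
    "AcquisitionPattern",
    "SensorModel",
    "ParasiticPlane",
    "SpeckleModel",
    "NoiseScene",
    "ShiftCalibration",
    "UnsupportedSceneError",
    "make_pattern",
    "tilt_for_shift",
    "shift_for_tilt",
    "calibrate_shift_map",
    "HologramSimulator",
    "simulate_frame",
    "simulate_stack",
]

RECTANGULAR = "rectangular"
CIRCULAR = "circular"


class UnsupportedSceneError(ValueError):
    """Scene cannot be simulated (e.g. scatterers at mixed heights)."""


@dataclass
class Scatterer:
    """A sub-micron object on the sample plane.

    ``strength`` is the complex transmission perturbation of the object:
    the sample transmission is ``t = 1 - strength * nanolens_gain *
    disk(diameter)``.  Its magnitude encodes absorption/scattering, its
    phase the optical path delay.  ``nanolens_gain`` phenomenologically
    represents the signal boost of a self-assembled nanolens.
    """

    x: float  # um
    y: float  # um
    z2: float = 400.0  # um above the sensor
    diameter: float = 200.0  # nm
    strength: complex = 0.6 - 0.5j
    nanolens_gain: float = 1.0

    def __post_init__(self) -> None:
        if not (self.z2 > 0):
            raise ValueError("z2 must be positive")
        if not (self.diameter > 0):
            raise ValueError("diameter must be positive")
        if abs(self.strength) > 1 + 1e-12:
            raise ValueError("|strength| must be <= 1")
        if self.nanolens_gain < 1:
            raise ValueError("nanolens_gain must be >= 1")


@dataclass
class AcquisitionPattern:
    """Ordered list of target hologram displacements on the sensor.

    ``shifts`` is an (N, 2) array of (dx, dy) in micrometres; ``kinds``
    tags each entry ``rectangular`` (resolution grid) or ``circular``
    (noise-averaging circles).
    """

    shifts: np.ndarray
    kinds: np.ndarray

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.shifts, dtype=float))
        k = np.asarray(self.kinds)
        if s.shape[1] != 2 or k.shape[0] != s.shape[0]:
            raise ValueError("shifts must be (N, 2) with one kind per entry")
        self.shifts, self.kinds = s, k

    def __len__(self) -> int:
        return self.shifts.shape[0]

    @property
    def n_rectangular(self) -> int:
        return int(np.sum(self.kinds == RECTANGULAR))

    @property
    def n_circular(self) -> int:
        return int(np.sum(self.kinds == CIRCULAR))

    def subset(self, kind: str) -> "AcquisitionPattern":
        m = self.kinds == kind
        return AcquisitionPattern(self.shifts[m], self.kinds[m])


def make_pattern(
    rect_n: int,
    rect_step: float,
    n_circles: int,
    radial_step: float,
    per_circle: int,
) -> AcquisitionPattern:
    """Build the acquisition pattern: a ``rect_n`` x ``rect_n`` sub-pixel
    grid centred on zero plus ``n_circles`` concentric circles.

    The platform's own pattern is ``make_pattern(14, 0.16, 12, 0.3, 30)``
    — 196 rectangular positions at ~0.16 um spacing plus 12 circles of
    30 positions at ~0.3 um radial spacing, 556 frames in total.
    """
    if rect_n < 0 or n_circles < 0 or per_circle < 0:
        raise ValueError("counts must be non-negative")
    if rect_n > 0 and not (rect_step > 0):
        raise ValueError("rect_step must be positive")
    if n_circles > 0 and per_circle > 0 and not (radial_step > 0):
        raise ValueError("radial_step must be positive")
    shifts: list[tuple[float, float]] = []
    kinds: list[str] = []
    if rect_n > 0:
        offs = (np.arange(rect_n) - (rect_n - 1) / 2.0) * rect_step
        for dy in offs:
            for dx in offs:
                shifts.append((dx, dy))
                kinds.append(RECTANGULAR)
    for k in range(1, n_circles + 1):
        r = k * radial_step
        for j in range(per_circle):
            ang = 2 * np.pi * j / per_circle
            shifts.append((r * np.cos(ang), r * np.sin(ang)))
            kinds.append(CIRCULAR)
    if not shifts:
        shifts, kinds = [(0.0, 0.0)], [RECTANGULAR]
    return AcquisitionPattern(np.array(shifts), np.array(kinds))


def tilt_for_shift(shift, z2: float) -> tuple[float, float]:
    """Beam tilt (theta_x, theta_y) in degrees producing a given
    hologram displacement (dx, dy) in um at sample height ``z2``."""
    if not (z2 > 0):
        raise ValueError("z2 must be positive")
    dx, dy = float(shift[0]), float(shift[1])
    return (math.degrees(math.atan(dx / z2)), math.degrees(math.atan(dy / z2)))


def shift_for_tilt(tilt_deg, z: float) -> tuple[float, float]:
    """Lateral displacement (um) of a plane at height ``z`` under a beam
    tilt (theta_x, theta_y) in degrees; inverse of :func:`tilt_for_shift`."""
    tx, ty = float(tilt_deg[0]), float(tilt_deg[1])
    return (z * math.tan(math.radians(tx)), z * math.tan(math.radians(ty)))


@dataclass
class ShiftCalibration:
    """Linear through-origin tilt(deg) -> shift(um) map, one slope per axis."""

    slope: np.ndarray  # um per degree, shape (2,) or scalar array

    def shift_for_tilt(self, tilt_deg) -> np.ndarray:
        return np.asarray(tilt_deg, dtype=float) * self.slope

    def tilt_for_shift(self, shift_um) -> np.ndarray:
        return np.asarray(shift_um, dtype=float) / self.slope


def calibrate_shift_map(tilts_deg, shifts_um) -> ShiftCalibration:
    """Least-squares through-origin slope per axis from >= 3 observed
    (tilt, measured shift) pairs — the platform's one-time galvo
    calibration from three reference tilts.
    """
    t = np.asarray(tilts_deg, dtype=float)
    s = np.asarray(shifts_um, dtype=float)
    if t.shape != s.shape:
        raise ValueError("tilts and shifts must have matching shapes")
    if t.ndim == 1:
        t = t[:, None]
        s = s[:, None]
        squeeze = True
    else:
        squeeze = False
    if t.shape[0] < 3:
        raise ValueError("at least 3 calibration observations are required")
    denom = np.sum(t * t, axis=0)
    if np.any(denom <= 0):
        raise ValueError("degenerate calibration: tilts have no spread on some axis")
    slope = np.sum(t * s, axis=0) / denom
    return ShiftCalibration(slope=slope[0] * np.ones(1) if squeeze else slope)


@dataclass
class SensorModel:
    """Bayer CMOS sensor response (defaults follow a 1.12 um RGGB imager)."""

    pixel_pitch: float = 1.12  # um
    bayer: str = "RGGB"  # or "mono"
    bit_depth: int = 16
    read_noise_sigma: float = 2.0  # counts
    shot_noise: bool = True
    gain: float = 20000.0  # counts per unit intensity
    rb_response: float = 0.0  # red/blue sensitivity at 266 nm rel. to green

    def __post_init__(self) -> None:
        if not (self.pixel_pitch > 0):
            raise ValueError("pixel_pitch must be positive")
        if self.bit_depth not in (8, 10, 12, 16):
            raise ValueError("bit_depth must be one of 8, 10, 12, 16")
        if self.bayer not in ("RGGB", "mono"):
            raise ValueError("bayer must be 'RGGB' or 'mono'")

    @classmethod
    def noiseless(cls, **kw) -> "SensorModel":
        kw.setdefault("shot_noise", False)
        kw.setdefault("read_noise_sigma", 0.0)
        return cls(**kw)


@dataclass
class ParasiticPlane:
    """An oblique plane-wave reflection at a height != z2 producing
    background interference fringes that shift differently under tilt.

    A negative height represents a virtual reflection plane below the
    sensor (multiple reflections inside the cover/sensor stack): its
    fringes move opposite to the sample holograms under tilt.
    """

    height: float  # um; may be negative (virtual plane below the sensor)
    amplitude: float  # relative to unit background
    orientation_deg: float = 0.0
    freq: float = 0.15  # fringe spatial frequency, 1/um

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.height == 0:
            raise ValueError("height must be non-zero")


@dataclass
class SpeckleModel:
    """Frozen complex Gaussian speckle field at a parasitic plane."""

    height: float = 1000.0  # um
    correlation_length: float = 5.0  # um
    contrast: float = 0.05  # rms amplitude relative to background
    seed: int = 20170309  # frozen: part of the scene, not the shot noise

    def __post_init__(self) -> None:
        if self.contrast < 0 or self.correlation_length <= 0:
            raise ValueError("invalid speckle parameters")


@dataclass
class NoiseScene:
    """Coherent background structure from out-of-sample planes."""

    parasitic_planes: list = dfield(
        default_factory=lambda: [
            ParasiticPlane(height=1000.0, amplitude=0.02, orientation_deg=20.0, freq=0.12),
            ParasiticPlane(height=5000.0, amplitude=0.015, orientation_deg=110.0, freq=0.2),
        ]
    )
    speckle: SpeckleModel | None = dfield(default_factory=SpeckleModel)

    @classmethod
    def quiet(cls) -> "NoiseScene":
        return cls(parasitic_planes=[], speckle=None)


def _deposit_scene(scene, shape, pitch) -> np.ndarray:
    """Sample-plane transmission t(x,y) = 1 - sum strength*gain*disk."""
    t = np.ones(shape, dtype=np.complex128)
    ny, nx = shape
    for s in scene:
        amp = complex(s.strength) * s.nanolens_gain
        r = s.diameter / 2000.0  # nm -> um radius
        cx, cy = s.x / pitch, s.y / pitch
        if 2 * r < pitch:
            # deep sub-cell object: deposit the area-integrated
            # perturbation bilinearly onto the 4 nearest cells.
            w = amp * (np.pi * r * r / pitch**2)
            ix, iy = int(np.floor(cx)), int(np.floor(cy))
            fx, fy = cx - ix, cy - iy
            for (jy, jx), ww in (
                ((iy, ix), (1 - fy) * (1 - fx)),
                ((iy, ix + 1), (1 - fy) * fx),
                ((iy + 1, ix), fy * (1 - fx)),
                ((iy + 1, ix + 1), fy * fx),
            ):
                if 0 <= jy < ny and 0 <= jx < nx:
                    t[jy, jx] -= w * ww
        else:
            half = int(np.ceil(r / pitch)) + 2
            iy0, iy1 = max(0, int(cy) - half), min(ny, int(cy) + half + 1)
            ix0, ix1 = max(0, int(cx) - half), min(nx, int(cx) + half + 1)
            yy = np.arange(iy0, iy1)[:, None] - cy
            xx = np.arange(ix0, ix1)[None, :] - cx
            dist = np.hypot(yy, xx) * pitch
            cov = np.clip((r - dist) / pitch + 0.5, 0.0, 1.0)
            t[iy0:iy1, ix0:ix1] -= amp * cov
    return t


class HologramSimulator:
    """Forward model of the acquisition, reusable across frames.

    The sensor-plane field of every optical plane (sample + parasitic)
    is computed once at zero tilt on a fine grid; each frame then only
    applies the per-plane lateral shift ``z_plane * tan(theta)`` via a
    spectral phase ramp, sums coherently, and digitizes.
    """

    def __init__(
        self,
        scene,
        sensor: SensorModel | None = None,
        noise: NoiseScene | None = None,
        shape: tuple[int, int] = (256, 256),
        subsample: int = 4,
        wavelength: float = 0.266,
        z2: float | None = None,
    ) -> None:
        self.scene = list(scene)
        self.sensor = sensor or SensorModel()
        self.noise = noise if noise is not None else NoiseScene()
        self.shape = tuple(shape)
        self.subsample = int(subsample)
        self.wavelength = wavelength

        z2s = {s.z2 for s in self.scene}
        if len(z2s) > 1:
            raise UnsupportedSceneError("all scatterers must share a single sample height z2")
        self.z2 = float(z2s.pop()) if z2s else float(z2 if z2 is not None else 400.0)
        for p in self.noise.parasitic_planes:
            if abs(p.height - self.z2) < 1e-9:
                raise ValueError("parasitic plane height must differ from the sample z2")
        if self.noise.speckle is not None and abs(self.noise.speckle.height - self.z2) < 1e-9:
            raise ValueError("speckle plane height must differ from the sample z2")

        fine_shape = (self.shape[0] * self.subsample, self.shape[1] * self.subsample)
        self.fine_pitch = self.sensor.pixel_pitch / self.subsample

        t = _deposit_scene(self.scene, fine_shape, self.fine_pitch).astype(np.complex64)
        u_obj = propagate(ComplexField(t, self.fine_pitch, wavelength), self.z2)
        # (plane height, sensor-plane spectrum) pairs
        self._planes: list[tuple[float, np.ndarray]] = [
            (self.z2, sfft.fft2(u_obj.values.astype(np.complex64)))
        ]
        for p in self.noise.parasitic_planes:
            f = self._parasitic_field(p, fine_shape)
            u = propagate(ComplexField(f, self.fine_pitch, wavelength), p.height)
            self._planes.append((p.height, sfft.fft2(u.values.astype(np.complex64))))
        sp = self.noise.speckle
        if sp is not None and sp.contrast > 0:
            f = self._speckle_field(sp, fine_shape)
            u = propagate(ComplexField(f, self.fine_pitch, wavelength), sp.height)
            self._planes.append((sp.height, sfft.fft2(u.values.astype(np.complex64))))
        self._fy = sfft.fftfreq(fine_shape[0], d=self.fine_pitch).astype(np.float64)
        self._fx = sfft.fftfreq(fine_shape[1], d=self.fine_pitch).astype(np.float64)

    def _parasitic_field(self, p: ParasiticPlane, shape) -> np.ndarray:
        y = np.arange(shape[0])[:, None] * self.fine_pitch
        x = np.arange(shape[1])[None, :] * self.fine_pitch
        th = math.radians(p.orientation_deg)
        phase = 2 * np.pi * p.freq * (x * math.cos(th) + y * math.sin(th))
        return (p.amplitude * np.exp(1j * phase)).astype(np.complex64)

    def _speckle_field(self, sp: SpeckleModel, shape) -> np.ndarray:
        rng = np.random.default_rng(sp.seed)
        g = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        fy = sfft.fftfreq(shape[0], d=self.fine_pitch)[:, None]
        fx = sfft.fftfreq(shape[1], d=self.fine_pitch)[None, :]
        sigma_f = 1.0 / (2 * np.pi * sp.correlation_length)
        h = np.exp(-(fx**2 + fy**2) / (2 * sigma_f**2))
        f = sfft.ifft2(sfft.fft2(g) * h)
        rms = np.sqrt(np.mean(np.abs(f) ** 2))
        return (f * (sp.contrast / rms)).astype(np.complex64)

    def sensor_intensity(self, tilt_deg=(0.0, 0.0)) -> np.ndarray:
        """Noise-free intensity integrated over pixel apertures."""
        tanx = math.tan(math.radians(float(tilt_deg[0])))
        tany = math.tan(math.radians(float(tilt_deg[1])))
        spec = np.zeros_like(self._planes[0][1])
        for z, f in self._planes:
            sx, sy = z * tanx, z * tany
            ry = np.exp(-2j * np.pi * self._fy * sy).astype(np.complex64)
            rx = np.exp(-2j * np.pi * self._fx * sx).astype(np.complex64)
            spec += f * ry[:, None] * rx[None, :]
        u = sfft.ifft2(spec)
        inten = (u.real**2 + u.imag**2).astype(np.float32)
        s = self.subsample
        ny, nx = self.shape
        return inten.reshape(ny, s, nx, s).mean(axis=(1, 3))

    def frame(self, tilt_deg=(0.0, 0.0), seed: int | None = None) -> np.ndarray:
        """One digitized raw frame at the given beam tilt (degrees)."""
        stochastic = self.sensor.shot_noise or self.sensor.read_noise_sigma > 0
        if stochastic and seed is None:
            raise ValueError("a seed is required when shot/read noise is enabled")
        counts = self.sensor_intensity(tilt_deg).astype(np.float64) * self.sensor.gain
        if self.sensor.bayer == "RGGB":
            ny, nx = counts.shape
            gmask = (np.arange(ny)[:, None] + np.arange(nx)[None, :]) % 2 == 1
            counts = np.where(gmask, counts, counts * self.sensor.rb_response)
        if stochastic:
            rng = np.random.default_rng(seed)
            if self.sensor.shot_noise:
                counts = rng.poisson(np.clip(counts, 0, None)).astype(np.float64)
            if self.sensor.read_noise_sigma > 0:
                counts = counts + rng.normal(0.0, self.sensor.read_noise_sigma, counts.shape)
        full = 2**self.sensor.bit_depth - 1
        return np.clip(np.rint(counts), 0, full).astype(np.uint16)


def demo_scene(z2: float = 400.0) -> list[Scatterer]:
    """Packaged demonstration scene for a 128x128-frame acquisition.

    Three nanolens-enhanced 300 nm beads plus a cluster of three 2.5 um
    dust specks near the field centre.  The dust cluster is the visible
    sample-plane mark used for shift registration; the detection chain
    reports the three beads as validated particles and rejects the
    marks' own candidates via the focus criteria.
    """
    scene = [
        Scatterer(x=30.0, y=32.0, z2=z2, diameter=300, strength=0.7 - 0.55j, nanolens_gain=35.0),
        Scatterer(x=110.0, y=40.0, z2=z2, diameter=300, strength=0.7 - 0.55j, nanolens_gain=35.0),
        Scatterer(x=45.0, y=108.0, z2=z2, diameter=300, strength=0.7 - 0.55j, nanolens_gain=35.0),
    ]
    for fx, fy in [(70.0, 68.0), (75.5, 72.2), (66.9, 75.0)]:
        scene.append(Scatterer(x=fx, y=fy, z2=z2, diameter=2500, strength=0.9 - 0.3j))
    return scene


def simulate_frame(
    scene,
    tilt_deg=(0.0, 0.0),
    sensor: SensorModel | None = None,
    noise: NoiseScene | None = None,
    seed: int | None = None,
    shape: tuple[int, int] = (256, 256),
    subsample: int = 4,
    wavelength: float = 0.266,
    z2: float | None = None,
) -> np.ndarray:
    """Single raw frame (convenience wrapper over HologramSimulator)."""
    sim = HologramSimulator(scene, sensor, noise, shape, subsample, wavelength, z2)
    return sim.frame(tilt_deg, seed=seed)


def simulate_stack(
    scene,
    pattern: AcquisitionPattern,
    sensor: SensorModel | None = None,
    noise: NoiseScene | None = None,
    seed: int | None = 0,
    shape: tuple[int, int] = (256, 256),
    subsample: int = 4,
    wavelength: float = 0.266,
    z2: float | None = None,
) -> FrameStack:
    """Simulate one raw frame per pattern entry.

    Per-frame noise seeds are derived deterministically from ``seed``;
    the nominal shifts stored in the returned stack are the pattern's
    target displacements (the ground truth, since the simulated galvo is
    ideal).
    """
    sim = HologramSimulator(scene, sensor, noise, shape, subsample, wavelength, z2)
    n = len(pattern)
    ss = np.random.SeedSequence(seed)
    frame_seeds = ss.generate_state(n) % (2**31)
    frames = np.empty((n, *sim.shape), dtype=np.uint16)
    for k in range(n):
        tilt = tilt_for_shift(pattern.shifts[k], sim.z2)
        frames[k] = sim.frame(tilt, seed=int(frame_seeds[k]))
    return FrameStack(
        frames=frames,
        nominal_shifts=pattern.shifts.copy(),
        pitch=sim.sensor.pixel_pitch,
        kinds=pattern.kinds.copy(),
    )
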