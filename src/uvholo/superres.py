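"""Pixel super-resolution with circular averaging.

Turns a stack of sub-pixel-shifted raw Bayer frames into one
noise-suppressed high-resolution hologram:

1. ``green_fill`` — only the green Bayer channel responds to 266 nm;
   red/blue pixels are filled with the mean of their green neighbours.
2. ``normalize_frame`` — each frame is divided by its own Gaussian
   low-pass, removing the slowly varying illumination envelope while
   keeping the holographic fringes.
3. ``estimate_shifts`` — sub-pixel registration of every frame against
   frame 0 using a fiducial window on the sample plane, so the
   shift-and-add step locks to the sample-plane holograms (not to the
   parasitic background, which moves differently).
4. ``shift_and_add`` — frames are accumulated onto a ``factor``-times
   finer grid at their negated shifts.  Rectangular-grid frames supply
   the sub-pixel sampling diversity; the extra circularly shifted
   frames are redundant for resolution but smear out coherent noise
   that does not co-move with the sample plane (circular averaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .fields import lowpass

__all__ = [
    "FrameStack",
    "HighResHologram",
    "NoFiducialError",
    "green_fill",
    "normalize_frame",
    "estimate_shifts",
    "shift_and_add",
]


class NoFiducialError(ValueError):
    """Registration window lacks contrast; fall back to nominal shifts."""


@dataclass
class FrameStack:
    """Raw (or preprocessed) low-resolution frames with their shifts.

    ``nominal_shifts`` are the target hologram displacements (um) from
    the acquisition pattern; ``estimated_shifts`` is filled in by
    :func:`estimate_shifts`.
    """

    frames: np.ndarray  # (N, H, W)
    nominal_shifts: np.ndarray  # (N, 2) um, (dx, dy)
    pitch: float  # um
    estimated_shifts: np.ndarray | None = None
    kinds: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (N, H, W) array")
        s = np.atleast_2d(np.asarray(self.nominal_shifts, dtype=float))
        if s.shape != (f.shape[0], 2):
            raise ValueError("one (dx, dy) nominal shift per frame is required")
        self.frames, self.nominal_shifts = f, s

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shifts(self) -> np.ndarray:
        """Estimated shifts if available, otherwise nominal."""
        return self.estimated_shifts if self.estimated_shifts is not None else self.nominal_shifts

    def select(self, mask) -> "FrameStack":
        mask = np.asarray(mask)
        return FrameStack(
            frames=self.frames[mask],
            nominal_shifts=self.nominal_shifts[mask],
            pitch=self.pitch,
            estimated_shifts=None if self.estimated_shifts is None else self.estimated_shifts[mask],
            kinds=None if self.kinds is None else self.kinds[mask],
        )


@dataclass
class HighResHologram:
    """Super-resolved hologram on the upsampled grid.

    ``values`` is real for a plain intensity hologram and complex after
    digital object peeling.  ``coverage`` counts accumulated samples per
    cell (0 marks interpolated cells).
    """

    values: np.ndarray
    pitch: float  # um
    coverage: np.ndarray | None = None
    wavelength: float = 0.266  # um

    def __post_init__(self) -> None:
        if np.asarray(self.values).ndim != 2:
            raise ValueError("hologram must be 2-D")
        if not (self.pitch > 0):
            raise ValueError("pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def green_fill(frame: np.ndarray, pattern: str = "RGGB") -> np.ndarray:
    """Fill red/blue Bayer positions with the mean of their 4-connected
    green neighbours (edges: mean of the available neighbours).

    In an RGGB mosaic the green pixels sit on one checkerboard parity,
    so every red/blue pixel has exclusively green 4-neighbours.
    """
    if pattern != "RGGB":
        raise ValueError("only the RGGB pattern is supported")
    f = np.asarray(frame, dtype=np.float64)
    if f.ndim != 2 or f.shape[0] % 2 or f.shape[1] % 2:
        raise ValueError("frame must be 2-D with even dimensions")
    ny, nx = f.shape
    green = (np.arange(ny)[:, None] + np.arange(nx)[None, :]) % 2 == 1
    p = np.full((ny + 2, nx + 2), np.nan)
    p[1:-1, 1:-1] = f
    neigh = np.stack(
        [p[:-2, 1:-1], p[2:, 1:-1], p[1:-1, :-2], p[1:-1, 2:]]
    )
    with np.errstate(invalid="ignore"):
        fill = np.nanmean(neigh, axis=0)
    out = f.copy()
    out[~green] = fill[~green]
    return out


def normalize_frame(frame: np.ndarray, cutoff: float = 0.05, pitch: float = 1.12) -> np.ndarray:
    """Divide a frame by its own Gaussian low-pass (std ``cutoff`` in
    1/um), flattening the illumination envelope; output mean ~ 1."""
    f = np.asarray(frame, dtype=np.float64)
    if not np.any(f):
        raise ValueError("cannot normalize an all-zero frame")
    bg = lowpass(f, cutoff, pitch=pitch)
    floor = np.finfo(float).eps * max(1.0, float(np.abs(bg).max()))
    return f / np.maximum(bg, floor)


def _constrained_subpixel_shift(
    ref: np.ndarray, mov: np.ndarray, max_shift_px: float, upsample_factor: int
) -> tuple[float, float]:
    """Cross-correlation peak restricted to |shift| <= max_shift_px,
    refined on an upsampled grid by explicit (matrix) DFT evaluation."""
    import scipy.fft as sfft

    cross = sfft.fft2(mov) * np.conj(sfft.fft2(ref))
    cc = sfft.ifft2(cross).real
    ny, nx = cc.shape
    m = int(np.ceil(max_shift_px))
    idx = np.r_[0 : m + 1, -m:0]
    sub = cc[np.ix_(idx % ny, idx % nx)]
    iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
    d0y, d0x = float(idx[iy]), float(idx[ix])
    fy = sfft.fftfreq(ny)
    fx = sfft.fftfreq(nx)
    step = 1.0 / upsample_factor
    dys = np.arange(d0y - 1.0, d0y + 1.0 + step / 2, step)
    dxs = np.arange(d0x - 1.0, d0x + 1.0 + step / 2, step)
    ky = np.exp(2j * np.pi * np.outer(dys, fy))
    kx = np.exp(2j * np.pi * np.outer(fx, dxs))
    fine = (ky @ cross @ kx).real
    jy, jx = np.unravel_index(np.argmax(fine), fine.shape)
    # negate to match the phase_cross_correlation convention (the shift
    # that registers the moving frame back onto the reference)
    return -dys[jy], -dxs[jx]


def estimate_shifts(
    stack: FrameStack,
    window: tuple[slice, slice] | None = None,
    upsample_factor: int = 100,
    min_contrast: float = 1e-4,
    anchor: str = "frame0",
    max_shift_px: float | None = None,
    apodize: float = 0.5,
) -> np.ndarray:
    """Sub-pixel hologram shifts of every frame via upsampled
    cross-correlation restricted to a fiducial ``window`` (a pair of
    slices) containing a visible sample-plane object.

    Returns (N, 2) shifts in um, (dx, dy), with the same sign convention
    as the nominal shifts (the hologram's displacement on the sensor);
    also stored on ``stack.estimated_shifts``.

    ``anchor`` fixes the arbitrary global offset of relative shifts:
    ``"frame0"`` reports displacements relative to frame 0 (frame 0 gets
    shift zero); ``"nominal"`` translates the estimates so their mean
    matches the nominal table's mean (registration then corrects only
    the residual positioning errors, keeping the pattern's absolute
    frame of reference).  ``max_shift_px`` optionally restricts the
    correlation-peak search to plausible displacements, a guard against
    locking onto strong periodic background fringes.  ``apodize`` sets
    the taper fraction of the Tukey window applied (after mean removal)
    to suppress cropping-boundary bias; 0 disables it.
    """
    frames = stack.frames
    if anchor not in ("frame0", "nominal"):
        raise ValueError("anchor must be 'frame0' or 'nominal'")
    if window is None:
        h, w = frames.shape[1:]
        window = (slice(h // 4, 3 * h // 4), slice(w // 4, 3 * w // 4))
    ref = np.asarray(frames[0][window], dtype=np.float64)
    scale = float(np.abs(ref).mean()) or 1.0
    if ref.std() / scale < min_contrast:
        raise NoFiducialError(
            "fiducial window is flat; choose a window containing a visible "
            "object, or fall back to the nominal shift table"
        )
    if apodize > 0:
        from scipy.signal.windows import tukey

        taper = np.outer(tukey(ref.shape[0], apodize), tukey(ref.shape[1], apodize))
    else:
        taper = 1.0

    def _prep(win: np.ndarray) -> np.ndarray:
        return (win - win.mean()) * taper

    ref = _prep(ref)
    shifts = np.zeros((len(stack), 2))
    for k in range(1, len(stack)):
        mov = _prep(np.asarray(frames[k][window], dtype=np.float64))
        if max_shift_px is not None:
            dy, dx = _constrained_subpixel_shift(ref, mov, max_shift_px, upsample_factor)
        else:
            (dy, dx), _, _ = phase_cross_correlation(
                ref, mov, upsample_factor=upsample_factor, normalization=None
            )
        # the returned displacement maps the moving frame back onto the
        # reference; the hologram itself moved by the negation of that.
        shifts[k] = (-dx * stack.pitch, -dy * stack.pitch)
    if anchor == "nominal":
        shifts = shifts - shifts.mean(axis=0) + stack.nominal_shifts.mean(axis=0)
    stack.estimated_shifts = shifts
    return shifts


def _fill_holes(values: np.ndarray, covered: np.ndarray) -> np.ndarray:
    """Fill uncovered cells by iterated local interpolation from
    covered neighbours (normalized 3x3 box convolution)."""
    out = np.where(covered, values, 0.0)
    known = covered.astype(np.float64)
    kernel = np.ones((3, 3))
    while not known.all():
        num = ndimage.convolve(out * known, kernel, mode="nearest")
        den = ndimage.convolve(known, kernel, mode="nearest")
        new = (den > 0) & (known == 0)
        if not new.any():  # pragma: no cover - disconnected empty grid
            break
        out[new] = num[new] / den[new]
        known[new] = 1.0
    return out


def shift_and_add(
    stack: FrameStack,
    shifts: np.ndarray | None = None,
    factor: int = 4,
    wavelength: float = 0.266,
) -> HighResHologram:
    """Shift-and-add pixel super-resolution.

    Every frame — rectangular and circular alike — is placed onto a
    ``factor``-times finer grid at the nearest cell displaced by its
    negated shift, then per-cell sums are divided by coverage.  With
    1.12 um native frames and ``factor=4`` the output pitch is 0.28 um.

    Cells never hit by any frame (sparse patterns) are filled by local
    interpolation from covered neighbours and flagged with coverage 0.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if shifts is None:
        shifts = stack.shifts
    shifts = np.atleast_2d(np.asarray(shifts, dtype=float))
    if shifts.shape != (len(stack), 2):
        raise ValueError("one (dx, dy) shift per frame is required")

    n, h, w = stack.frames.shape
    hr_pitch = stack.pitch / factor
    acc = np.zeros((h * factor, w * factor), dtype=np.float64)
    cov = np.zeros((h * factor, w * factor), dtype=np.int64)
    base = (factor - 1) / 2.0
    rows0 = np.arange(h) * factor
    cols0 = np.arange(w) * factor
    for k in range(n):
        dx, dy = shifts[k]
        oy = int(np.rint(base - dy / hr_pitch))
        ox = int(np.rint(base - dx / hr_pitch))
        rows = rows0 + oy
        cols = cols0 + ox
        rv = (rows >= 0) & (rows < h * factor)
        cv = (cols >= 0) & (cols < w * factor)
        idx = np.ix_(rows[rv], cols[cv])
        acc[idx] += stack.frames[k][np.ix_(rv.nonzero()[0], cv.nonzero()[0])]
        cov[idx] += 1
    covered = cov > 0
    vals = np.divide(acc, cov, out=np.zeros_like(acc), where=covered)
    if not covered.all():
        vals = _fill_holes(vals, covered)
    return HighResHologram(values=vals, pitch=hr_pitch, coverage=cov, wavelength=wavelength)
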