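"""Scalar optical fields and free-space propagation.

A sampled complex field ``U(x, y)`` is propagated by a signed distance
``dz`` through a homogeneous medium of refractive index ``n`` with the
angular-spectrum method: each plane-wave component ``(fx, fy)`` of its
2-D spectrum is multiplied by the transfer function

    H(fx, fy) = exp(i 2 pi dz sqrt((n/lambda)^2 - fx^2 - fy^2))

Components outside the propagating circle ``fx^2 + fy^2 <= (n/lambda)^2``
are evanescent and are attenuated with the corresponding real exponential
decay (never amplified, regardless of the sign of ``dz``).

Conventions
-----------
* All lateral lengths and ``dz`` are in micrometres; spatial frequencies
  in cycles per micrometre.
* Pixel centres, origin at the top-left sample, x rightward, y downward.
* z increases from the sensor toward the sample, so reconstruction of an
  in-line hologram back to the sample plane uses a negative ``dz``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.fft as sfft

__all__ = ["ComplexField", "propagate", "lowpass"]


@dataclass
class ComplexField:
    """A 2-D complex optical field on a regular grid.

    Parameters
    ----------
    values : ndarray of complex
        Field amplitudes (dimensionless, background-normalized).
    pitch : float
        Grid spacing in micrometres.
    wavelength : float
        Vacuum wavelength in micrometres (0.266 for the UV platform).
    medium_index : float
        Real refractive index of the propagation medium (default 1.0,
        i.e. the air gap between sample and sensor).
    """

    values: np.ndarray
    pitch: float
    wavelength: float = 0.266
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("field grid must be 2-D with at least 2 samples per axis")
        if not np.iscomplexobj(v):
            v = v.astype(np.complex128)
        self.values = v
        if not (self.pitch > 0):
            raise ValueError("pitch must be positive")
        if not (self.wavelength > 0):
            raise ValueError("wavelength must be positive")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ComplexField":
        return replace(self, values=self.values.copy())


def _transfer_function(
    shape: tuple[int, int],
    pitch: float,
    wavelength: float,
    medium_index: float,
    dz: float,
    dtype: np.dtype,
    keep_carrier: bool = False,
) -> np.ndarray:
    """Angular-spectrum transfer function on an FFT-ordered grid.

    By default the constant plane-wave carrier ``exp(i 2 pi dz n/lambda)``
    is factored out (phase referenced to the co-propagating illumination),
    so an on-axis plane wave keeps phase 0 at every height — the stable
    convention for comparing phase images across reconstruction heights.
    """
    fy = sfft.fftfreq(shape[0], d=pitch)[:, None]
    fx = sfft.fftfreq(shape[1], d=pitch)[None, :]
    f0 = medium_index / wavelength
    fz_sq = f0**2 - fx**2 - fy**2
    prop = fz_sq > 0
    # propagating part: pure phase; evanescent part: real decay using |dz|
    # so that back-propagation never amplifies evanescent components.
    h = np.empty(np.broadcast_shapes(fy.shape, fx.shape), dtype=np.complex128)
    carrier = f0 if not keep_carrier else 0.0
    h[prop] = np.exp(1j * 2 * np.pi * dz * (np.sqrt(fz_sq[prop]) - carrier))
    h[~prop] = np.exp(-2 * np.pi * abs(dz) * np.sqrt(-fz_sq[~prop]) - 1j * 2 * np.pi * dz * carrier)
    return h.astype(dtype)


def propagate(
    field: ComplexField, dz: float, pad_factor: int = 1, keep_carrier: bool = False
) -> ComplexField:
    """Propagate a field by a signed distance ``dz`` (micrometres).

    Positive ``dz`` moves the field toward the sample (away from the
    sensor); negative ``dz`` back-propagates.  Grid pitch and shape are
    preserved.

    Parameters
    ----------
    field : ComplexField
    dz : float
        Signed propagation distance, micrometres.
    pad_factor : int
        Zero-padding factor for the FFT (1 = periodic boundary).  Larger
        values suppress wrap-around of energy leaving the window at the
        cost of a larger transform.
    keep_carrier : bool
        If True, retain the absolute plane-wave carrier phase
        ``exp(i 2 pi dz n/lambda)`` (needed when comparing against
        absolute diffraction integrals).  Default False: phase is
        referenced to the co-propagating illumination, so phase images
        are comparable across heights.

    Returns
    -------
    ComplexField
        Propagated field with the same pitch and shape.
    """
    if not np.isscalar(dz) or not np.isfinite(dz):
        raise ValueError("dz must be a finite scalar")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    v = field.values
    if dz == 0:
        return field.copy()

    ny, nx = v.shape
    if pad_factor > 1:
        vp = np.zeros((ny * pad_factor, nx * pad_factor), dtype=v.dtype)
        vp[:ny, :nx] = v
    else:
        vp = v
    spec = sfft.fft2(vp)
    h = _transfer_function(
        vp.shape, field.pitch, field.wavelength, field.medium_index, float(dz),
        spec.dtype, keep_carrier=keep_carrier,
    )
    out = sfft.ifft2(spec * h)[:ny, :nx]
    return replace(field, values=np.ascontiguousarray(out))


def lowpass(image: np.ndarray, cutoff: float, pitch: float = 1.0) -> np.ndarray:
    """Frequency-domain Gaussian low-pass filter.

    The spectrum is multiplied by ``exp(-(fx^2+fy^2) / (2 cutoff^2))``
    where ``cutoff`` is the Gaussian standard deviation in cycles per
    micrometre; the mean (DC) value is preserved exactly.

    Works on real or complex images; a real input returns a real output.
    """
    if not (cutoff > 0):
        raise ValueError("cutoff must be positive")
    a = np.asarray(image)
    if a.ndim != 2:
        raise ValueError("image must be 2-D")
    fy = sfft.fftfreq(a.shape[0], d=pitch)[:, None]
    fx = sfft.fftfreq(a.shape[1], d=pitch)[None, :]
    h = np.exp(-(fx**2 + fy**2) / (2.0 * cutoff**2))
    out = sfft.ifft2(sfft.fft2(a) * h)
    if not np.iscomplexobj(a):
        return out.real.astype(a.dtype if np.issubdtype(a.dtype, np.floating) else np.float64)
    return out
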