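"""Hologram reconstruction: back-propagation, autofocus, object peeling.

An in-line intensity hologram is lifted to a complex field (square root
of the non-negative intensity with zero phase — the standard
single-shot treatment; no iterative phase retrieval is performed) and
back-propagated by the sample height ``z2`` with the angular-spectrum
method, yielding amplitude and phase images of the sample.

The optimal height ``z2*`` is where a particle's reconstruction shows
minimum amplitude or maximum phase (``autofocus``).

Large objects produce twin-image ripples that can bury nearby weak
particles; ``peel_objects`` forward-propagates the hologram to the twin
plane (-z2), replaces the thresholded object regions with the local
background, and returns the cleaned (now complex) hologram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .fields import ComplexField, propagate
from .superres import HighResHologram

__all__ = [
    "Reconstruction",
    "AutofocusResult",
    "lift_hologram",
    "backpropagate",
    "autofocus",
    "peel_objects",
]


@dataclass
class Reconstruction:
    """Amplitude/phase images of the sample at height ``z2``."""

    amplitude: np.ndarray
    phase: np.ndarray  # radians in (-pi, pi]
    z2: float  # um
    field: ComplexField
    hologram: HighResHologram | None = None


def lift_hologram(holo: HighResHologram) -> ComplexField:
    """Complex field at the sensor plane for a measured hologram.

    Real (intensity) holograms: sqrt of the intensity clamped at zero,
    zero phase.  Complex holograms (after peeling) are used directly.
    """
    v = np.asarray(holo.values)
    if np.iscomplexobj(v):
        u = v.astype(np.complex128)
    else:
        u = np.sqrt(np.clip(v, 0.0, None)).astype(np.complex128)
    return ComplexField(u, pitch=holo.pitch, wavelength=holo.wavelength)


def backpropagate(holo: HighResHologram, z2: float, pad_factor: int = 1) -> Reconstruction:
    """Back-propagate a hologram to the sample plane at height ``z2``."""
    if not (z2 > 0):
        raise ValueError("z2 must be positive")
    field = propagate(lift_hologram(holo), -z2, pad_factor=pad_factor)
    return Reconstruction(
        amplitude=np.abs(field.values),
        phase=np.angle(field.values),
        z2=float(z2),
        field=field,
        hologram=holo,
    )


@dataclass
class AutofocusResult:
    """Outcome of a focus scan: best height plus the metric curve."""

    z2: float  # um
    z_values: np.ndarray
    metric: np.ndarray
    criterion: str
    flat: bool = False


def autofocus(
    holo: HighResHologram,
    z_min: float,
    z_max: float,
    step: float,
    criterion: str = "min_amplitude",
    window: tuple[slice, slice] | None = None,
) -> AutofocusResult:
    """Scan reconstruction heights and return the focus optimum.

    ``min_amplitude`` minimizes the windowed amplitude minimum;
    ``max_phase`` maximizes the windowed phase maximum.  Ties break
    toward smaller ``z2``.  A flat metric (e.g. an empty hologram)
    returns ``z_min`` with ``flat=True`` and a warning.
    """
    if not (z_min < z_max):
        raise ValueError("z_min must be < z_max")
    if not (step > 0):
        raise ValueError("step must be positive")
    if criterion not in ("min_amplitude", "max_phase"):
        raise ValueError("criterion must be 'min_amplitude' or 'max_phase'")
    ny, nx = np.asarray(holo.values).shape
    if window is not None:
        wy, wx = window
        if (wy.start or 0) < 0 or (wx.start or 0) < 0 or (wy.stop or ny) > ny or (wx.stop or nx) > nx:
            raise ValueError("autofocus window lies outside the hologram grid")
    else:
        window = (slice(None), slice(None))

    import scipy.fft as sfft

    lifted = lift_hologram(holo)
    spec = sfft.fft2(lifted.values)
    from .fields import _transfer_function

    zs = np.arange(z_min, z_max + step / 2, step)
    metric = np.empty(zs.shape)
    for i, z in enumerate(zs):
        h = _transfer_function(
            lifted.shape, holo.pitch, holo.wavelength, 1.0, -float(z), spec.dtype
        )
        u = sfft.ifft2(spec * h)[window]
        if criterion == "min_amplitude":
            metric[i] = np.abs(u).min()
        else:
            metric[i] = np.angle(u).max()

    spread = np.ptp(metric)
    scale = max(np.abs(metric).max(), np.finfo(float).tiny)
    if spread / scale < 1e-9:
        warnings.warn("autofocus metric is flat; returning z_min", stacklevel=2)
        return AutofocusResult(float(zs[0]), zs, metric, criterion, flat=True)
    idx = int(np.argmin(metric) if criterion == "min_amplitude" else np.argmax(metric))
    return AutofocusResult(float(zs[idx]), zs, metric, criterion)


def _annulus_background(values: np.ndarray, mask: np.ndarray, width: int = 10) -> tuple[float, float]:
    """Median amplitude and phase in an annulus around the mask."""
    ring = ndimage.binary_dilation(mask, iterations=width) & ~mask
    if not ring.any():  # pragma: no cover - mask fills the field edge case
        ring = ~mask
    return float(np.median(np.abs(values[ring]))), float(np.median(np.angle(values[ring])))


def peel_objects(
    holo: HighResHologram,
    z2: float,
    phase_threshold: float,
    planes: tuple[str, ...] = ("twin",),
    dilation: int = 3,
    annulus_width: int = 10,
    max_mask_fraction: float = 0.5,
) -> HighResHologram:
    """Digitally peel strong objects from the hologram.

    At each requested plane (``"twin"`` at -z2 and/or ``"object"`` at
    +z2) the hologram field is propagated there, cells whose phase
    deviates from the background median by more than ``phase_threshold``
    (mask dilated by ``dilation`` cells) are replaced with the median
    amplitude/phase of an annulus around the mask, and the field is
    propagated back to the sensor plane.  The result is a complex
    hologram free of the peeled objects' artifacts.
    """
    if not (z2 > 0):
        raise ValueError("z2 must be positive")
    bad = set(planes) - {"twin", "object"}
    if bad:
        raise ValueError(f"unknown peeling planes: {sorted(bad)}")
    field = lift_hologram(holo)
    for plane in planes:
        # z increases sensor -> sample: the twin image lives at -z2, so
        # reaching it means propagating by +z2 from the sensor; the
        # object plane is reached by -z2 (back-propagation).
        dz = z2 if plane == "twin" else -z2
        u = propagate(field, dz)
        phase = np.angle(u.values)
        dev = phase - np.median(phase)
        mask = np.abs(dev) > phase_threshold
        if mask.mean() > max_mask_fraction:
            raise ValueError(
                "phase threshold masks more than half of the field; "
                "background is undefined"
            )
        if mask.any():
            if dilation > 0:
                mask = ndimage.binary_dilation(mask, iterations=dilation)
            bg_amp, bg_phase = _annulus_background(u.values, mask, annulus_width)
            vals = u.values.copy()
            vals[mask] = bg_amp * np.exp(1j * bg_phase)
            u = replace(u, values=vals)
        field = propagate(u, -dz)
    return HighResHologram(
        values=field.values,
        pitch=holo.pitch,
        coverage=holo.coverage,
        wavelength=holo.wavelength,
    )
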