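"""Mie forward-scattering radar cross section of PEC nanospheres.

Why it matters for lensless imaging: the smallest detectable particle is
set by the ratio of scattered to background light on the sensor.  The
forward-scatter radar cross section (RCS) of a sphere quantifies that
scattered power, and for a fixed sphere it grows steeply as the
illumination wavelength shrinks.  Comparing the RCS-vs-diameter curves
at two wavelengths therefore translates a known detection limit at one
wavelength into the equivalent limit at another.

The sphere is idealized as a perfect electric conductor (PEC), for which
the Mie coefficients are refractive-index free:

    a_n = j_n(x) / h1_n(x)
    b_n = [x j_n(x)]' / [x h1_n(x)]'

with size parameter ``x = pi d / lambda``, spherical Bessel ``j_n`` and
spherical Hankel of the first kind ``h1_n``.  The forward amplitude is
``S(0) = 1/2 sum_n (2n+1)(a_n + b_n)`` and the forward RCS

    sigma = 4 pi |S(0)|^2 / k^2 = (lambda^2 / pi) |S(0)|^2 .

All lengths in nanometres; cross sections in nm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect
from scipy.special import spherical_jn, spherical_yn

__all__ = [
    "RCSCurve",
    "min_terms",
    "pec_forward_rcs",
    "rcs_curve",
    "equivalent_diameter",
    "sphere_forward_rcs",
]


def min_terms(x: float) -> int:
    """Minimum Mie-series truncation order for size parameter ``x``.

    Uses the standard ``x + 4 x^(1/3) + 2`` rule.
    """
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def _pec_coefficients(x: float, n_max: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.arange(1, n_max + 1)
    jn = spherical_jn(n, x)
    djn = spherical_jn(n, x, derivative=True)
    yn = spherical_yn(n, x)
    dyn = spherical_yn(n, x, derivative=True)
    hn = jn + 1j * yn
    dhn = djn + 1j * dyn
    a = jn / hn
    # [x f(x)]' = f(x) + x f'(x)
    b = (jn + x * djn) / (hn + x * dhn)
    return n, a, b


def pec_forward_rcs(diameter: float, wavelength: float, n_terms: int | None = None) -> float:
    """Forward-scattering RCS (nm^2) of a PEC sphere.

    Parameters
    ----------
    diameter, wavelength : float
        Sphere diameter and vacuum wavelength, nanometres.
    n_terms : int, optional
        Series truncation order; at least the ``min_terms`` rule is
        always used.
    """
    if not (diameter > 0):
        raise ValueError("diameter must be positive")
    if not (wavelength > 0):
        raise ValueError("wavelength must be positive")
    x = np.pi * diameter / wavelength
    nmax = min_terms(x)
    if n_terms is not None:
        nmax = max(int(n_terms), 1)
        # honor an explicit truncation only if it is at least 1; used by
        # the dipole-limit cross-check.
    n, a, b = _pec_coefficients(x, nmax)
    s0 = 0.5 * np.sum((2 * n + 1) * (a + b))
    return float(wavelength**2 / np.pi * np.abs(s0) ** 2)


def sphere_forward_rcs(
    diameter: float, wavelength: float, refractive_index: complex, n_terms: int | None = None
) -> float:
    """Forward RCS (nm^2) of a homogeneous dielectric sphere.

    Standard Mie coefficients with relative index ``m``; provided for
    realism checks (e.g. polystyrene beads) — the detection-limit
    analysis itself uses the PEC idealization.
    """
    if not (diameter > 0 and wavelength > 0):
        raise ValueError("diameter and wavelength must be positive")
    m = complex(refractive_index)
    x = np.pi * diameter / wavelength
    mx = m * x
    nmax = max(min_terms(x), int(n_terms or 0))
    n = np.arange(1, nmax + 1)

    def psi(z, deriv=False):
        if deriv:
            return spherical_jn(n, z) + z * spherical_jn(n, z, derivative=True)
        return z * spherical_jn(n, z)

    jx = spherical_jn(n, x)
    yx = spherical_yn(n, x)
    hx = jx + 1j * yx
    psix = x * jx
    dpsix = jx + x * spherical_jn(n, x, derivative=True)
    xix = x * hx
    dxix = hx + x * (spherical_jn(n, x, derivative=True) + 1j * spherical_yn(n, x, derivative=True))
    jmx = spherical_jn(n, mx.real) if mx.imag == 0 else None
    if jmx is None:
        raise NotImplementedError("complex refractive index not supported")
    psimx = mx.real * jmx
    dpsimx = jmx + mx.real * spherical_jn(n, mx.real, derivative=True)
    a = (m * psimx * dpsix - psix * dpsimx) / (m * psimx * dxix - xix * dpsimx)
    b = (psimx * dpsix - m * psix * dpsimx) / (psimx * dxix - m * xix * dpsimx)
    s0 = 0.5 * np.sum((2 * n + 1) * (a + b))
    return float(wavelength**2 / np.pi * np.abs(s0) ** 2)


@dataclass
class RCSCurve:
    """Forward RCS as a function of diameter at a fixed wavelength."""

    wavelength: float  # nm
    diameters: np.ndarray  # nm, increasing
    rcs: np.ndarray  # nm^2
    n_terms: int

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        r = np.asarray(self.rcs, dtype=float)
        if d.ndim != 1 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be positive and strictly increasing")
        if r.shape != d.shape or np.any(r <= 0):
            raise ValueError("rcs must be positive and match diameters")
        self.diameters, self.rcs = d, r


def rcs_curve(diameters: np.ndarray, wavelength: float) -> RCSCurve:
    """Evaluate the PEC forward-RCS curve over a diameter grid (nm)."""
    d = np.asarray(diameters, dtype=float)
    rcs = np.array([pec_forward_rcs(di, wavelength) for di in d])
    nmax = min_terms(np.pi * d.max() / wavelength)
    return RCSCurve(wavelength=wavelength, diameters=d, rcs=rcs, n_terms=nmax)


def equivalent_diameter(
    d_ref: float,
    lambda_ref: float,
    lambda_target: float,
    bracket: tuple[float, float] = (1.0, 2000.0),
    tol: float = 0.01,
) -> float:
    """Diameter at ``lambda_target`` with the same forward RCS as
    ``d_ref`` at ``lambda_ref`` (all in nm).

    Solved by bisection of the RCS-vs-diameter curve; e.g. a 250 nm
    detection limit under green (532 nm) illumination maps to a much
    smaller equivalent diameter under 266 nm UV.
    """
    if not (d_ref > 0 and lambda_ref > 0 and lambda_target > 0):
        raise ValueError("all inputs must be positive")
    if lambda_target == lambda_ref:
        return float(d_ref)
    target = pec_forward_rcs(d_ref, lambda_ref)

    def f(d: float) -> float:
        return np.log(pec_forward_rcs(d, lambda_target)) - np.log(target)

    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise ValueError("target RCS not bracketed in the search interval")
    return float(bisect(f, lo, hi, xtol=tol))
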