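"""File formats: TIFF stacks for images, JSON for shifts/scenes/sidecars.

Raw frames are 16-bit TIFF stacks; processed images (super-resolved
holograms, reconstructions) are 32-bit float TIFFs with a JSON sidecar
carrying pitch/wavelength/height metadata.  Complex fields are stored
as a 2-page (amplitude, phase) float TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .simulate import AcquisitionPattern, Scatterer
from .superres import FrameStack, HighResHologram

__all__ = [
    "write_stack",
    "read_stack",
    "write_shifts",
    "read_shifts",
    "write_hologram",
    "read_hologram",
    "write_reconstruction",
    "write_scene",
    "read_scene",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, stack: FrameStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames), photometric="minisblack")
    write_shifts(_sidecar(path), stack)


def read_stack(path: str | Path, shifts_path: str | Path | None = None) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(Path(shifts_path or _sidecar(path)).read_text())
    return FrameStack(
        frames=frames,
        nominal_shifts=np.asarray(meta["nominal_shifts_um"], dtype=float),
        pitch=float(meta["pitch_um"]),
        estimated_shifts=(
            np.asarray(meta["estimated_shifts_um"], dtype=float)
            if meta.get("estimated_shifts_um") is not None
            else None
        ),
        kinds=np.asarray(meta["kinds"]) if meta.get("kinds") is not None else None,
    )


def write_shifts(path: str | Path, stack: FrameStack) -> None:
    meta = {
        "pitch_um": stack.pitch,
        "nominal_shifts_um": np.asarray(stack.nominal_shifts).tolist(),
        "estimated_shifts_um": (
            np.asarray(stack.estimated_shifts).tolist()
            if stack.estimated_shifts is not None
            else None
        ),
        "kinds": np.asarray(stack.kinds).tolist() if stack.kinds is not None else None,
    }
    Path(path).write_text(json.dumps(meta))


def read_shifts(path: str | Path) -> np.ndarray:
    meta = json.loads(Path(path).read_text())
    est = meta.get("estimated_shifts_um")
    return np.asarray(est if est is not None else meta["nominal_shifts_um"], dtype=float)


def write_hologram(path: str | Path, holo: HighResHologram) -> None:
    path = Path(path)
    v = np.asarray(holo.values)
    if np.iscomplexobj(v):
        pages = np.stack([np.abs(v), np.angle(v)]).astype(np.float32)
        kind = "complex"
    else:
        pages = v[None].astype(np.float32)
        kind = "real"
    tifffile.imwrite(path, pages)
    meta = {"pitch_um": holo.pitch, "wavelength_um": holo.wavelength, "kind": kind}
    _sidecar(path).write_text(json.dumps(meta))


def read_hologram(path: str | Path) -> HighResHologram:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("kind") == "complex":
        values = pages[0].astype(np.float64) * np.exp(1j * pages[1].astype(np.float64))
    else:
        values = (pages[0] if pages.ndim == 3 else pages).astype(np.float64)
    return HighResHologram(
        values=values, pitch=float(meta["pitch_um"]), wavelength=float(meta["wavelength_um"])
    )


def write_reconstruction(path: str | Path, recon) -> None:
    """Amplitude/phase as a 2-page float TIFF with a JSON sidecar."""
    path = Path(path)
    pages = np.stack([recon.amplitude, recon.phase]).astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {
        "pitch_um": recon.field.pitch,
        "wavelength_um": recon.field.wavelength,
        "z2_um": recon.z2,
        "pages": ["amplitude", "phase"],
    }
    _sidecar(path).write_text(json.dumps(meta))


def write_scene(path: str | Path, scene, z2: float | None = None) -> None:
    data = {
        "z2_um": z2,
        "scatterers": [
            {
                "x_um": s.x,
                "y_um": s.y,
                "z2_um": s.z2,
                "diameter_nm": s.diameter,
                "strength": [s.strength.real, s.strength.imag],
                "nanolens_gain": s.nanolens_gain,
            }
            for s in scene
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_scene(path: str | Path) -> list[Scatterer]:
    data = json.loads(Path(path).read_text())
    out = []
    for s in data["scatterers"]:
        re, im = s["strength"]
        out.append(
            Scatterer(
                x=s["x_um"],
                y=s["y_um"],
                z2=s.get("z2_um", 400.0),
                diameter=s["diameter_nm"],
                strength=complex(re, im),
                nanolens_gain=s.get("nanolens_gain", 1.0),
            )
        )
    return out
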