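"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields as dc_fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the imaging pipeline.

    Defaults follow the UV platform: 266 nm illumination, 1.12 um Bayer
    sensor, 4x super-resolution (0.28 um effective pitch), the
    196 + 360 frame acquisition pattern, and the three parabola focus
    criteria.
    """

    # optics / sensor
    wavelength: float = 0.266  # um
    pixel_pitch: float = 1.12  # um
    sr_factor: int = 4
    # acquisition pattern
    rect_n: int = 14
    rect_step: float = 0.16  # um
    n_circles: int = 12
    radial_step: float = 0.3  # um
    per_circle: int = 30
    # reconstruction / focus search
    z_min: float = 300.0  # um
    z_max: float = 500.0  # um
    z_step: float = 2.0  # um
    # multi-height averaging neighbourhood (half-range, step)
    avg_half: float = 20.0  # um
    avg_step: float = 1.0  # um
    # per-candidate focus curve
    focus_half_range: float = 40.0  # um
    focus_step: float = 2.0  # um
    window_radius: int = 5  # high-res cells
    # detection thresholds
    a_max: float = -9e-6  # compensated-phase units per um^2
    r2_min: float = 0.42
    z_tol: float = 15.0  # um
    k_sigma: float = 6.0
    min_size: int = 2  # cells
    # filtering cutoffs (Gaussian std, 1/um)
    cutoff_normalize: float = 0.05
    cutoff_background: float = 0.1
    # simulation
    sensor_shape: tuple = (256, 256)
    subsample: int = 4
    z2: float = 400.0  # um
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sensor_shape"] = list(self.sensor_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "sensor_shape" in d:
            d["sensor_shape"] = tuple(d["sensor_shape"])
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text) or {})

    def replace(self, **kw) -> "PipelineConfig":
        d = self.to_dict()
        d.update(kw)
        return self.from_dict(d)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed expanded from the global seed.

        Uses a fixed stage index as a SeedSequence spawn key so stages
        are decorrelated but fully reproducible.
        """
        stages = {"simulate": 0, "superres": 1, "reconstruct": 2, "detect": 3}
        if stage not in stages:
            raise ValueError(f"unknown stage: {stage}")
        import numpy as np

        ss = np.random.SeedSequence(self.seed, spawn_key=(stages[stage],))
        return int(ss.generate_state(1)[0] % (2**31))
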