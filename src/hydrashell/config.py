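"""Analysis configuration: YAML-loadable, hashable for provenance.

Defaults mirror the published analysis parameters: 0.5 A grid step, bulk
shell 8.0–10.0 A from the surface, hydration-site threshold 2.0x bulk with
a 1.4 A (0.14 nm) exclusion radius, 4 A cylinder diameter with 20 deg angle
step, and a 1 ns superstructured threshold.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    topology: str | None = None
    trajectory: str | None = None
    dt: float | None = None                  # ps; required if file has no times

    grid_step: float = 0.5                   # angstrom
    grid_padding: float = 12.0
    bulk_shell: tuple[float, float] = (8.0, 10.0)

    min_density: float = 2.0                 # bulk units
    site_radius: float = 1.4                 # angstrom (0.14 nm)

    cylinder_diameter: float = 4.0
    angle_step: float = 20.0                 # degrees
    rdf_bin_width: float = 0.1
    rdf_r_max: float = 12.0

    capture_radius: float = 1.4
    survival_mode: str = "continuous"
    max_lag: float | None = None             # ps; None -> auto
    superstructured_threshold: float = 1000.0

    hbond_distance: float = 3.5
    hbond_angle: float = 150.0
    contact_cutoff: float = 3.5

    surface_metric: str = "center"           # center | vdw
    sasa_probe: float = 1.4
    sasa_points: int = 960

    compute_hbonds: bool = True
    compute_sasa: bool = True
    seed: int = 0

    def __post_init__(self):
        self.bulk_shell = tuple(self.bulk_shell)
        if self.bulk_shell[0] >= self.bulk_shell[1]:
            raise ParameterError("bulk shell lower bound must be < upper")
        for name in ("grid_step", "min_density", "site_radius",
                     "cylinder_diameter", "angle_step", "rdf_bin_width",
                     "capture_radius", "superstructured_threshold",
                     "hbond_distance", "contact_cutoff"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.survival_mode not in ("continuous", "intermittent"):
            raise ParameterError("survival_mode must be continuous or "
                                 "intermittent")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["bulk_shell"] = list(self.bulk_shell)
        d["schema_version"] = SCHEMA_VERSION
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.pop("schema_version", None)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
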