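"""Run configuration: YAML-backed description of a reproducible run."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .simulate import AcquisitionConfig

__all__ = ["RunConfig"]

MODES = ("simulate", "fit", "spectral", "phasor", "compare")

#: Required top-level blocks/keys per mode, checked before any compute.
REQUIRED: dict[str, tuple[str, ...]] = {
    "simulate": ("probe",),
    "fit": ("inputs",),
    "spectral": ("inputs",),
    "phasor": ("inputs",),
    "compare": ("inputs", "wavelength_nm"),
}


@dataclass
class RunConfig:
    """Everything one CLI invocation needs; the seed is recorded in all
    outputs so any table can be traced back to its inputs."""

    mode: str
    seed: int = 0
    out_dir: Path = Path("flimkit_out")
    probe: str | None = None
    acquisition: dict = field(default_factory=dict)
    photons: int = 1_000_000
    image: dict | None = None
    inputs: list[str] = field(default_factory=list)
    fit: dict = field(default_factory=dict)
    gp: dict | None = None
    wavelength_nm: float | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        for key in REQUIRED[self.mode]:
            value = getattr(self, key)
            if value in (None, [], ""):
                raise ConfigError(
                    f"mode {self.mode!r} requires the {key!r} block/field"
                )
        self.out_dir = Path(self.out_dir)
        n = self.fit.get("n", 2)
        if n not in (1, 2, 3):
            raise ConfigError("fit.n must be 1, 2 or 3")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def acquisition_config(self) -> AcquisitionConfig:
        return AcquisitionConfig(seed=self.seed, **self.acquisition)
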