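"""Run configuration: every pipeline constant in one place.

Defaults are the values used throughout the analysis: B3LYP frequency
scaling 0.98, instrument width fraction 0.01, NCI density thresholds
18 / 15 nm⁻³ with reduced-gradient cutoff 0.5, 10 Å conformer-graph edge
threshold, 400 K Gibbs temperature, and the "admp-b3lyp-n07d" time-step
power-law profile.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ValidationError


@dataclass
class RunConfig:
    scale_factor: float = 0.98
    width_fraction: float = 0.01
    nci_rho_hbond: float = 18.0        # nm⁻³
    nci_rho_weak: float = 15.0         # nm⁻³
    nci_s_max: float = 0.5
    graph_threshold: float = 10.0      # Å
    temperature: float = 400.0         # K
    power_law_profile: str = "admp-b3lyp-n07d"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scale_factor", "width_fraction", "nci_rho_hbond",
                     "nci_rho_weak", "nci_s_max", "graph_threshold",
                     "temperature"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def write_manifest(self, path: str | Path, **extra) -> None:
        """Machine-readable run manifest (parameters, seeds, extras)."""
        from . import __version__

        manifest = {"pepspec_version": __version__,
                    "config": self.to_dict(), **extra}
        Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
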