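"""Experiment configuration: one human-editable YAML mapping.

Validated up front (unknown keys rejected) so a typo fails before any
pipeline stage runs.  The configuration records every tunable decision —
threshold method, positivity rule per marker, shape definitions — and is
echoed into reports so results are traceable to their settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .assays import PositivityRule

__all__ = ["ExperimentConfig", "load_config", "save_config"]

SCHEMA_VERSION = 1

#: marker channel -> (compartment, constitutive).  Intensity summaries
#: average over all microglia for constitutive markers and over positive
#: cells only for inducible ones.
DEFAULT_MARKERS: dict[str, tuple[str, bool]] = {
    "pu1": ("nucleus", True),
    "ki67": ("nucleus", False),
    "cebpb": ("nucleus", False),
    "hla": ("cell", False),
    "dap12": ("cell", True),
    "csf1r": ("cell", True),
    "igf1r": ("cell", True),
}


@dataclass
class ExperimentConfig:
    schema_version: int = SCHEMA_VERSION
    # channel roles
    nuclei_channel: str = "nuclei"
    surface_channel: str = "surface"
    cargo_channel: str = "cargo"
    marker_channels: dict[str, tuple[str, bool]] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )
    # segmentation
    nucleus_min_area: float = 25.0
    nucleus_max_area: float = 500.0
    nucleus_seed_min_distance: int = 5
    cell_min_area: float = 80.0
    # positivity
    positivity_k: float = 3.0
    cargo_min_area_fraction: float = 0.02
    # morphometry
    eff_definition: str = "moment"  # or "feret"
    perimeter_method: str = "subpixel"  # or "crofton" | "contour"
    # statistics
    paired: bool = False
    alpha: float = 0.05
    # bookkeeping
    seed: int = 0

    def rule_for(self, marker: str) -> PositivityRule:
        compartment, _ = self.marker_channels.get(marker, ("nucleus", False))
        return PositivityRule(
            marker=marker, compartment=compartment, k=self.positivity_k,
            min_area_fraction=self.cargo_min_area_fraction,
        )

    def is_constitutive(self, marker: str) -> bool:
        return self.marker_channels.get(marker, ("nucleus", False))[1]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["marker_channels"] = {k: list(v) for k, v in self.marker_channels.items()}
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a YAML config; unknown keys raise, missing keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "marker_channels" in raw:
        raw["marker_channels"] = {
            k: tuple(v) for k, v in raw["marker_channels"].items()
        }
    cfg = ExperimentConfig(**raw)
    if cfg.schema_version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported config schema_version {cfg.schema_version} "
            f"(expected {SCHEMA_VERSION})"
        )
    if cfg.eff_definition not in ("moment", "feret"):
        raise ValueError(f"unknown eff_definition {cfg.eff_definition!r}")
    if cfg.perimeter_method not in ("subpixel", "crofton", "contour"):
        raise ValueError(f"unknown perimeter_method {cfg.perimeter_method!r}")
    if not (0 < cfg.alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return cfg


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
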