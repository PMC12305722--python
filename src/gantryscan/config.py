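"""Run configuration: a single YAML file describing phantom, gantry, scan
and scorer, parsed into validated dataclasses.

YAML is the one accepted format; TOML (or anything else) is rejected with a
clear error so configs stay uniform.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._util import ValidationError
from .geometry import GantryGeometry
from .phantom import LesionSpec
from .scoring import ScorerSpec
from .search import ScanConfig

__all__ = ["PhantomConfig", "RunConfig", "load_config", "dump_config", "default_config"]


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom block: geometry plus texture of the digital tissue block."""

    extent: tuple[float, float, float] = (160.0, 120.0, 60.0)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_echogenicity: float = 0.35
    texture_amplitude: float = 0.05
    texture_smoothing: float = 1.5
    lesions: tuple[LesionSpec, ...] = ()


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for a reproducible end-to-end run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    geometry: GantryGeometry = field(default_factory=GantryGeometry)
    scan: ScanConfig = field(default_factory=ScanConfig)
    scorer: ScorerSpec = field(default_factory=ScorerSpec)
    seed: int = 0

    def validate(self) -> None:
        stages = {
            "phantom": self._validate_phantom,
            "scan": self.scan.validate,
        }
        for stage, fn in stages.items():
            try:
                fn()
            except ValidationError as err:
                raise ValidationError(f"[{stage}] {err}") from err

    def _validate_phantom(self) -> None:
        from .phantom import _validate_lesions  # deferred to avoid cycle at import

        if any(s <= 0 for s in self.phantom.spacing):
            raise ValidationError("spacing must be positive")
        _validate_lesions(self.phantom.lesions, self.phantom.extent)


def _as_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_dict(v) for v in obj]
    return obj


def dump_config(config: RunConfig) -> str:
    """Serialize a RunConfig to canonical YAML (stable key order)."""
    return yaml.safe_dump(_as_dict(config), sort_keys=True, default_flow_style=False)


def _build(cls, block: dict, stage: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValidationError(f"[{stage}] unknown keys: {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValidationError) as err:
        raise ValidationError(f"[{stage}] {err}") from err


def parse_config(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    known = {"phantom", "geometry", "scan", "scorer", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
    phantom_block = dict(data.get("phantom", {}))
    lesions = tuple(
        LesionSpec(tuple(l["center"]), tuple(l["radii"]),
                   l.get("echogenicity", -0.25))
        for l in phantom_block.pop("lesions", [])
    )
    for key in ("extent", "spacing"):
        if key in phantom_block:
            phantom_block[key] = tuple(phantom_block[key])
    cfg = RunConfig(
        phantom=_build(PhantomConfig, {**phantom_block, "lesions": lesions}, "phantom"),
        geometry=_build(GantryGeometry, dict(data.get("geometry", {})), "geometry"),
        scan=_build(ScanConfig, dict(data.get("scan", {})), "scan"),
        scorer=_build(ScorerSpec, dict(data.get("scorer", {})), "scorer"),
        seed=int(data.get("seed", 0)),
    )
    cfg.validate()
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if path.suffix.lower() in (".toml", ".ini", ".json"):
        raise ValidationError(
            f"unsupported config format {path.suffix!r}: configs are YAML"
        )
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_config(data or {})


def default_config() -> RunConfig:
    """The package defaults (no lesions; add a layout or use a fixture)."""
    return RunConfig()
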