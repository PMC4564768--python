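"""Pipeline configuration: TOML-backed, strictly validated, provenance-logged."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .landmarker import DEFAULT_SCHEME
from .synthflower import FlowerParams
from .volseg import SegmentationConfig


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline in one (TOML-serialisable) object.

    Unknown keys in a config file are rejected rather than ignored so that
    typos cannot silently fall back to defaults.
    """

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    flower: FlowerParams = field(default_factory=FlowerParams)
    scheme: tuple[int, int, int] = DEFAULT_SCHEME
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 100
    geometric_circle_fit: bool = False
    front_scheme: int = 6
    side_scheme: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.scheme) != 3 or any(int(v) != v or v < 0 for v in self.scheme):
            raise ValueError("scheme must be three non-negative integers")
        object.__setattr__(self, "scheme", tuple(int(v) for v in self.scheme))
        if self.gpa_tol <= 0 or self.gpa_max_iter < 1:
            raise ValueError("gpa_tol must be > 0 and gpa_max_iter >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scheme"] = list(self.scheme)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _check_unknown(section: dict, cls, where: str) -> None:
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown config keys in [{where}]: {sorted(unknown)}")


def load_config(path) -> PipelineConfig:
    """Read a TOML config file; missing keys take defaults, unknown keys raise."""
    raw = tomllib.loads(Path(path).read_text())
    seg = raw.pop("segmentation", {})
    flower = raw.pop("flower", {})
    _check_unknown(seg, SegmentationConfig, "segmentation")
    _check_unknown(flower, FlowerParams, "flower")
    _check_unknown(raw, PipelineConfig, "top level")
    top = {k: (tuple(v) if k == "scheme" else v) for k, v in raw.items()}
    return PipelineConfig(segmentation=SegmentationConfig(**seg),
                          flower=FlowerParams(**flower), **top)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)}")


def save_config(config: PipelineConfig, path) -> None:
    """Write the effective settings back to TOML (round-trips exactly)."""
    d = config.to_dict()
    seg = d.pop("segmentation")
    flower = d.pop("flower")
    lines = [f"{k} = {_toml_value(v)}" for k, v in d.items()]
    lines.append("\n[segmentation]")
    lines += [f"{k} = {_toml_value(v)}" for k, v in seg.items() if v is not None]
    lines.append("\n[flower]")
    lines += [f"{k} = {_toml_value(v)}" for k, v in flower.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_provenance(path, config: PipelineConfig, seed: int, stage: str) -> None:
    """Drop a provenance JSON next to an artifact: config hash, versions, seed."""
    import numpy
    import scipy
    import skimage

    from . import __version__

    Path(path).write_text(json.dumps({
        "stage": stage,
        "seed": seed,
        "config_sha256_16": config.digest(),
        "config": config.to_dict(),
        "versions": {
            "floramorph": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
        },
    }, indent=2))
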