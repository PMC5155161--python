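"""Flat key-value run configuration and provenance headers."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .analysis import ClusterParams
from .instrument import CameraModel, GratingGeometry
from .localization import LocalizationParams
from .rendering import RenderConfig

__all__ = ["RunConfig", "read_config", "write_config", "provenance_header"]


@dataclass
class RunConfig:
    """End-to-end run configuration: instrument constants, thresholds, seed.

    Serialized as a flat ``key=value`` text file; CLI flags override file
    values.
    """

    seed: int = 1
    camera: CameraModel = field(default_factory=CameraModel)
    geometry: GratingGeometry = field(default_factory=GratingGeometry)
    localization: LocalizationParams = field(default_factory=LocalizationParams)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    rendering: RenderConfig = field(default_factory=RenderConfig)

    def flat_items(self) -> dict[str, object]:
        out: dict[str, object] = {"seed": self.seed}
        for section, obj in [
            ("camera", self.camera),
            ("grating", self.geometry),
            ("localization", self.localization),
            ("cluster", self.clustering),
            ("render", self.rendering),
        ]:
            for f in fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(t) for t in v)
                out[f"{section}.{f.name}"] = v
        return out

    def digest(self) -> str:
        text = "\n".join(f"{k}={v}" for k, v in sorted(self.flat_items().items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for k, v in config.flat_items().items():
            fh.write(f"{k}={v}\n")


def _coerce(raw: str, like):
    if isinstance(like, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(like, int):
        return int(raw)
    if isinstance(like, float):
        return float(raw)
    if isinstance(like, tuple):
        parts = raw.split(",")
        return tuple(type(t)(p) for t, p in zip(like, parts))
    return raw


def read_config(path) -> RunConfig:
    """Parse a flat key=value config file (unknown keys are ignored)."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()
    cfg = RunConfig()
    sections = {
        "camera": cfg.camera,
        "grating": cfg.geometry,
        "localization": cfg.localization,
        "cluster": cfg.clustering,
        "render": cfg.rendering,
    }
    updates: dict[str, dict] = {name: {} for name in sections}
    for key, raw in kv.items():
        if key == "seed":
            cfg.seed = int(raw)
            continue
        if "." not in key:
            continue
        section, name = key.split(".", 1)
        obj = sections.get(section)
        if obj is None:
            continue
        current = {f.name: getattr(obj, f.name) for f in fields(obj)}
        if name in current:
            updates[section][name] = _coerce(raw, current[name])
    from dataclasses import replace

    cfg.camera = replace(cfg.camera, **updates["camera"])
    cfg.geometry = replace(cfg.geometry, **updates["grating"])
    cfg.localization = replace(cfg.localization, **updates["localization"])
    cfg.clustering = replace(cfg.clustering, **updates["cluster"])
    cfg.rendering = replace(cfg.rendering, **updates["render"])
    return cfg


def provenance_header(config: RunConfig) -> str:
    from . import __version__

    return f"spaint v{__version__} config={config.digest()} seed={config.seed}"
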