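"""Configuration files, trace files and run manifests.

Configs are flat YAML (or JSON) mappings of :class:`ModelConfig` fields; an
empty file yields the full default configuration.  Traces are plain CSV with
a commented header carrying the node coordinate, time step and config hash,
written at full float precision so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .solver import ModelConfig, VoltageTrace

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "write_trace",
    "read_trace",
    "RunManifest",
]

_TRACE_MAGIC = "# fraccable-trace v1"


class ConfigError(ValueError):
    """A configuration file violates the schema."""


def load_config(path) -> ModelConfig:
    """Read a YAML/JSON config; missing keys take the standard defaults."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" and text.strip():
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(data).__name__}")
    known = set(ModelConfig().to_dict())
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"{path}: unknown config field(s) {sorted(unknown)}; "
            f"valid fields are {sorted(known)}"
        )
    try:
        return ModelConfig.from_dict(data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(cfg: ModelConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def write_trace(trace: VoltageTrace, path) -> None:
    """Write one voltage trace as commented-header CSV, full precision."""
    if len(trace.v) == 0:
        raise ValueError("refusing to write an empty trace")
    lines = [
        _TRACE_MAGIC,
        f"# x_cm={trace.x!r}",
        f"# dt_ms={trace.dt!r}",
        f"# t0_ms={trace.t0!r}",
        f"# stim_start_ms={trace.stim_start!r}",
        f"# config_hash={trace.meta.get('config_hash', '')}",
        "time_ms,v_mV",
    ]
    t = trace.t
    lines.extend(f"{float(t[i])!r},{float(trace.v[i])!r}"
                 for i in range(len(trace.v)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path) -> VoltageTrace:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != _TRACE_MAGIC:
        raise ValueError(f"{path}: not a fraccable trace file")
    header = {}
    body_start = None
    for i, line in enumerate(lines[1:], start=1):
        if line.startswith("# "):
            key, _, value = line[2:].partition("=")
            header[key] = value
        elif line == "time_ms,v_mV":
            body_start = i + 1
            break
        else:
            raise ValueError(f"{path}: malformed header line {line!r}")
    if body_start is None:
        raise ValueError(f"{path}: missing column header")
    required = {"x_cm", "dt_ms", "t0_ms", "stim_start_ms"}
    missing = required - set(header)
    if missing:
        raise ValueError(f"{path}: header missing {sorted(missing)}")
    rows = [line.split(",") for line in lines[body_start:] if line]
    if not rows:
        raise ValueError(f"{path}: empty trace")
    t = np.array([float(r[0]) for r in rows])
    v = np.array([float(r[1]) for r in rows])
    dt = float(header["dt_ms"])
    if len(t) > 1 and np.max(np.abs(np.diff(t) - dt)) > 1e-9:
        raise ValueError(f"{path}: sample spacing disagrees with dt_ms header")
    stim = header["stim_start_ms"]
    return VoltageTrace(
        x=float(header["x_cm"]),
        dt=dt,
        v=v,
        t0=float(header["t0_ms"]),
        stim_start=None if stim == "None" else float(stim),
        meta={"config_hash": header.get("config_hash", "")},
    )


@dataclass
class RunManifest:
    """Reproducibility sidecar written next to every CLI run's outputs."""

    config: dict
    config_hash: str
    version: str
    wall_time_s: float
    outputs: list = field(default_factory=list)
    created: str = ""

    @classmethod
    def collect(cls, cfg: ModelConfig | None, outputs,
                wall_time_s: float) -> "RunManifest":
        from . import __version__

        return cls(
            config=cfg.to_dict() if cfg is not None else {},
            config_hash=cfg.config_hash() if cfg is not None else "",
            version=__version__,
            wall_time_s=float(wall_time_s),
            outputs=[str(p) for p in outputs],
            created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path) -> None:
        for out in self.outputs:
            if not Path(out).exists():
                raise FileNotFoundError(f"manifest lists missing output {out}")
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
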