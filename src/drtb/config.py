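"""Run configuration: defaults, YAML/JSON loading, and grid parsing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import MADFilterParams, ScanConfig
from .preprocess import MeanshiftParams, PMParams

__all__ = ["RunConfig", "parse_grid", "DEFAULTS"]

DEFAULTS: dict = {
    "pm": {"iterations": 10, "kappa": 0.1, "step": 0.2,
           "conductance": "exponential"},
    "meanshift": {"bandwidth": 0.1},
    "hadamard": {"eps": 1e-6},
    "drtb": {
        "levels": "0.01:0.99:0.01",
        "sigma_grid": "0.5:150.0:0.5",
        "bin_width": 1.0,
        "connectivity": 8,
        "mad_b": 1.4826,
        "mad_cutoff": 3.0,
        "min_area": 4,
        "invert": False,
        "drop_border": False,
        "unique_edges": False,
    },
    "evaluation": {"radius": 30.0},
}


def parse_grid(spec) -> np.ndarray:
    """Parse a grid given as ``start:stop:step`` (inclusive stop, within
    floating-point slack) or as an explicit list of numbers."""
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError(f"grid spec must be START:STOP:STEP, got {spec!r}")
        start, stop, step = (float(p) for p in parts)
        if step <= 0 or stop < start:
            raise ValueError(f"bad grid spec {spec!r}")
        n = int(round((stop - start) / step)) + 1
        return np.round(start + step * np.arange(n), 10)
    return np.asarray(spec, dtype=np.float64)


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Materialized parameter blocks for a full run."""

    pm: PMParams = field(default_factory=PMParams)
    meanshift: MeanshiftParams = field(default_factory=MeanshiftParams)
    eps: float = 1e-6
    scan: ScanConfig = field(default_factory=ScanConfig)
    radius: float = 30.0
    raw: dict = field(default_factory=lambda: dict(DEFAULTS))

    @classmethod
    def from_dict(cls, override: dict | None = None) -> "RunConfig":
        cfg = _merge(DEFAULTS, override or {})
        drtb = cfg["drtb"]
        scan = ScanConfig(
            levels=parse_grid(drtb["levels"]),
            sigma_grid=parse_grid(drtb["sigma_grid"]),
            bin_width=float(drtb["bin_width"]),
            connectivity=int(drtb["connectivity"]),
            mad=MADFilterParams(b=float(drtb["mad_b"]),
                                cutoff=float(drtb["mad_cutoff"])),
            min_area=int(drtb["min_area"]),
            invert=bool(drtb["invert"]),
            drop_border=bool(drtb["drop_border"]),
            unique_edges=bool(drtb["unique_edges"]),
        )
        return cls(
            pm=PMParams(**cfg["pm"]),
            meanshift=MeanshiftParams(bandwidth=float(
                cfg["meanshift"]["bandwidth"])),
            eps=float(cfg["hadamard"]["eps"]),
            scan=scan,
            radius=float(cfg["evaluation"]["radius"]),
            raw=cfg,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(Path(path), "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable short hash of the effective configuration."""
        blob = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
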