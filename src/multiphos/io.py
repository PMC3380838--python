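"""Configuration files, run manifests, and tabular output.

Model configurations and sampling policies are plain YAML key-value files
validated against the dataclass schemas (unknown keys are rejected with
their paths).  Screen tables are written as CSV with percentages at the
one-decimal table precision plus a full-precision JSON sidecar, and every
output is accompanied by a manifest (seed, config/policy digests, package
version, timings) sufficient to re-run it exactly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .crn import ConfigurationError
from .models import ModelConfig
from .sampling import SamplingPolicy
from .screen import ScreenSummary

__all__ = ["load_config", "load_policy", "dump_config", "dump_policy",
           "write_table", "RunManifest"]

_TUPLE_FIELDS = {"rate_range", "conc_range", "atot_range", "km_bin",
                 "km_ratio_bin", "kd_low_range", "kd_high_range"}


def _from_mapping(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS and value is not None:
            if not (isinstance(value, (list, tuple)) and len(value) == 2):
                raise ConfigurationError(f"{path}.{key}: expected a 2-element list")
            value = (float(value[0]), float(value[1]))
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> ModelConfig:
    """Read and validate a ModelConfig from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(ModelConfig, data, str(path))


def load_policy(path) -> SamplingPolicy:
    """Read and validate a SamplingPolicy from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(SamplingPolicy, data, str(path))


def _to_plain(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def dump_config(config: ModelConfig, path=None) -> str:
    text = yaml.safe_dump(_to_plain(config), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def dump_policy(policy: SamplingPolicy, path=None) -> str:
    text = yaml.safe_dump(_to_plain(policy), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def write_table(summary: ScreenSummary, path) -> None:
    """CSV with the screening column contract (percent at one decimal,
    deterministic row order) plus a full-precision JSON sidecar."""
    path = Path(path)
    table = summary.table.copy()
    table = table.sort_values(["n_sites", "off_scaffold", "on_scaffold", "bin_lo"],
                              kind="stable").reset_index(drop=True)
    sidecar = {
        "fold_threshold": summary.fold_threshold,
        "seed": summary.seed,
        "rows": table.to_dict(orient="records"),
    }
    table["percent"] = table["percent"].map(lambda v: f"{v:.1f}")
    table["se_percent"] = table["se_percent"].map(lambda v: f"{v:.1f}")
    table.to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    seed: int
    config_digest: Optional[str] = None
    policy_digest: Optional[str] = None
    package_version: str = ""
    elapsed_s: float = 0.0
    failure_counts: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    @classmethod
    def start(cls, command: str, seed: int, config: Optional[ModelConfig] = None,
              policy: Optional[SamplingPolicy] = None, **extra) -> "RunManifest":
        from . import __version__

        m = cls(command=command, seed=seed, package_version=__version__, extra=extra)
        if config is not None:
            m.config_digest = _digest(dump_config(config))
        if policy is not None:
            m.policy_digest = _digest(dump_policy(policy))
        m._t0 = time.perf_counter()
        return m

    def finish(self, path) -> None:
        self.elapsed_s = time.perf_counter() - getattr(self, "_t0", time.perf_counter())
        payload = {k: v for k, v in dataclasses.asdict(self).items()}
        Path(str(path) + ".manifest.json").write_text(json.dumps(payload, indent=2))
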