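"""Run manifests, config files and result serialization.

Output layout of a run directory:

* ``curves.csv`` — long-form curves with columns
  (kind, chain_id, K, observable, value);
* ``metrics.json`` — per kind and observable the across-chain
  batch-means asymptotic-variance mean/std;
* ``manifest.json`` — everything needed to reproduce the run: seeds,
  config digest, wall times, warnings.

Configs are YAML with top-level keys ``preset``, ``kinds``, ``seed``,
``overrides`` (preset-field overrides) and ``ksd``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .errors import InvalidInputError
from .experiments import ExperimentPreset, PRESET_NAMES, get_preset
from .perturbations import KINDS, canonical_kind

__all__ = ["RunManifest", "config_digest", "load_config", "write_outputs"]


def _tool_version():
    try:
        return version("irrlangevin")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def config_digest(payload: dict) -> str:
    """Digest of a (nested) config; stable under key reordering."""
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    tool_version: str = field(default_factory=_tool_version)
    config: dict = field(default_factory=dict)
    config_digest: str = ""
    base_seed: int = 0
    chain_seeds: Dict[str, List[int]] = field(default_factory=dict)
    start_time: float = 0.0
    end_time: float = 0.0
    warnings: List[str] = field(default_factory=list)

    def start(self):
        self.start_time = time.time()
        return self

    def finish(self):
        self.end_time = time.time()
        return self

    def to_json_dict(self):
        out = dataclasses.asdict(self)
        out["config_digest"] = self.config_digest or config_digest(self.config)
        return out


_CONFIG_KEYS = {"preset", "kinds", "seed", "overrides", "ksd", "paper_scale"}
_KSD_KEYS = {"enabled", "max_k", "chains", "points"}


def _coerce_overrides(preset: ExperimentPreset, overrides: dict) -> dict:
    fields = {f.name: f for f in dataclasses.fields(preset)}
    clean = {}
    for key, value in overrides.items():
        if key not in fields:
            raise InvalidInputError(
                f"unknown override key {key!r}; valid keys: {sorted(fields)}")
        current = getattr(preset, key)
        if isinstance(current, bool):
            if not isinstance(value, bool):
                raise InvalidInputError(f"override {key!r} must be boolean")
        elif isinstance(current, (int, float)):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise InvalidInputError(
                    f"override {key!r} must be numeric, got {value!r}")
        clean[key] = value
    return clean


def load_config(path):
    """Parse and validate a YAML run config.

    Returns ``(preset, normalized config dict)``; the preset already has
    the overrides applied.  Unknown keys anywhere are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError("config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    name = raw.get("preset", "gaussian")
    if name not in PRESET_NAMES:
        raise InvalidInputError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    preset = get_preset(name, paper_scale=bool(raw.get("paper_scale", False)))
    overrides = raw.get("overrides") or {}
    if not isinstance(overrides, dict):
        raise InvalidInputError("'overrides' must be a mapping")
    overrides = _coerce_overrides(preset, overrides)
    preset = preset.replace(**overrides)
    kinds = raw.get("kinds", list(KINDS))
    if isinstance(kinds, str):
        kinds = [k.strip() for k in kinds.split(",") if k.strip()]
    kinds = [canonical_kind(k) for k in kinds]
    ksd_cfg = raw.get("ksd") or {}
    if not isinstance(ksd_cfg, dict):
        raise InvalidInputError("'ksd' must be a mapping")
    unknown = set(ksd_cfg) - _KSD_KEYS
    if unknown:
        raise InvalidInputError(f"unknown ksd config keys: {sorted(unknown)}")
    normalized = {
        "preset": name,
        "kinds": kinds,
        "seed": int(raw.get("seed", 0)),
        "overrides": overrides,
        "ksd": {"enabled": bool(ksd_cfg.get("enabled", False)),
                "max_k": int(ksd_cfg.get("max_k", 10**4)),
                "chains": int(ksd_cfg.get("chains", 5)),
                "points": int(ksd_cfg.get("points", 15))},
        "paper_scale": bool(raw.get("paper_scale", False)),
    }
    return preset, normalized


def write_outputs(outdir, reports, manifest: RunManifest):
    """Write curves.csv, metrics.json and manifest.json into ``outdir``."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = [rep.curves_frame() for rep in reports.values()]
    curves = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["kind", "chain_id", "K",
                                         "observable", "value"]))
    curves.to_csv(outdir / "curves.csv", index=False)
    metrics = {kind: {
        "avar_mean": rep.to_json_dict()["avar_mean"],
        "avar_std": rep.to_json_dict()["avar_std"],
        "n_chains": rep.n_chains,
        "n_failed": rep.n_failed,
    } for kind, rep in reports.items()}
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2,
                                                    sort_keys=True))
    (outdir / "manifest.json").write_text(
        json.dumps(manifest.to_json_dict(), indent=2, sort_keys=True,
                   default=str))
    return outdir
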