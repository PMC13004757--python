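"""Run configuration and persistence.

Configs are plain YAML/JSON with an explicit schema version; unknown
keys are rejected by name.  ``persist_run`` writes the spike record,
results, config copy and seed together with content hashes into a
manifest, removing partial output on failure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import yaml

from .core.params import ParameterError
from .core.record import SpikeRecord
from .mmn import REFERENCE_PARAMS, ModelParams

__all__ = ["RunConfig", "load_config", "save_config", "persist_run"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    protocol: str = "frequency_deviant"
    rate: float = 2.0
    n_per_pop: int = 40
    rel_sd: float = 0.3
    sigma: float = 25.0             # ms, rate-curve smoothing
    seed: int = 0
    net_seed: Optional[int] = None
    dt: float = 0.1
    ablate: List[str] = field(default_factory=list)
    extra_delay: float = 0.0
    nmda_block: bool = False
    jitter_theta: float = 0.0
    params: Dict = field(default_factory=dict)   # ModelParams overrides

    def model_params(self) -> ModelParams:
        return dataclasses.replace(REFERENCE_PARAMS, **self.params)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ParameterError(f"unknown config keys: {unknown}")
    cfg = RunConfig(**raw)
    if cfg.schema_version != SCHEMA_VERSION:
        raise ParameterError(
            f"unsupported schema_version {cfg.schema_version} (expected {SCHEMA_VERSION})"
        )
    if not isinstance(cfg.seed, int) or isinstance(cfg.seed, bool):
        raise ParameterError("seed must be an integer")
    param_fields = {f.name for f in dataclasses.fields(ModelParams)}
    bad = sorted(set(cfg.params) - param_fields)
    if bad:
        raise ParameterError(f"unknown model parameter keys: {bad}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def persist_run(
    record: SpikeRecord,
    results: Dict,
    out_dir,
    config: Optional[RunConfig] = None,
) -> Dict:
    """Write all run artifacts into ``out_dir`` and return the manifest.

    Artifacts: ``spikes.tsv`` (+ JSON sidecar), ``results.json``,
    optionally ``config.yaml``, and ``manifest.json`` listing every file
    with its SHA-256.  On any write failure the partially written
    directory contents created by this call are removed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    try:
        spike_path = out_dir / "spikes.tsv"
        record.save(spike_path)
        written += [spike_path, spike_path.with_suffix(".tsv.json")]

        results_path = out_dir / "results.json"
        with open(results_path, "w") as fh:
            json.dump(results, fh, indent=1, default=str)
        written.append(results_path)

        if config is not None:
            cfg_path = out_dir / "config.yaml"
            save_config(config, cfg_path)
            written.append(cfg_path)

        manifest = {
            "seed": record.seed,
            "t_end": record.t_end,
            "n_spikes": record.n_spikes,
            "artifacts": {p.name: _sha256(p) for p in written},
        }
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
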