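"""YAML configuration loading and run-reproducibility manifests.

A run manifest records everything needed to reproduce a QC run
byte-identically: the resolved parameter set, input file checksums, the
master seed, stage wall-clock times and the variant counts at each filter
stage.  It is written atomically (temp file + rename) at run end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path

import yaml

from .pipeline import QCParams
from .simulation import SimConfig


def _from_mapping(cls, mapping: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("block_size_range", "rho_range", "maf_range"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_qc_params(path) -> QCParams:
    """Load QCParams from a YAML mapping; unknown keys are a hard error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(QCParams, data)


def load_sim_config(path) -> SimConfig:
    """Load SimConfig from a YAML mapping; unknown keys are a hard error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(SimConfig, data)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    params,
    input_paths: dict | None = None,
    counts: dict | None = None,
    timings: dict | None = None,
) -> dict:
    """Write a JSON run manifest atomically; returns the manifest dict."""
    from . import __version__

    manifest = {
        "tool_version": __version__,
        "params": dataclasses.asdict(params),
        "seed": getattr(params, "seed", None),
        "inputs": {
            name: {"path": str(p), "sha256": _checksum(p)}
            for name, p in (input_paths or {}).items()
        },
        "counts": counts or {},
        "wall_clock_s": timings or {},
    }
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return manifest
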