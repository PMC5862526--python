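"""Readers and writers for the pipeline's tidy CSV/TSV tables.

Every file the pipeline writes starts with a ``#``-prefixed comment
header recording the tool version, a hash of the configuration, the
seed, and a timestamp (the timestamp is excluded from the hash).  All
readers skip ``#`` comment lines, so outputs round-trip.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import schema as S
from .errors import SchemaError
from .normalization import FeatureMatrix, validate_ct_table

__all__ = [
    "read_ct_table",
    "read_table",
    "write_table",
    "read_feature_matrix",
    "write_feature_matrix",
    "load_config",
    "config_hash",
]


def config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _header_lines(seed=None, config=None, extra: dict | None = None) -> list[str]:
    lines = [
        f"# iegdecode {__version__}",
        f"# config_hash: {config_hash(config)}",
        f"# seed: {seed}",
        f"# written: {datetime.now(timezone.utc).isoformat(timespec='seconds')}",
    ]
    for key, val in (extra or {}).items():
        lines.append(f"# {key}: {val}")
    return lines


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def write_table(
    df: pd.DataFrame,
    path,
    seed=None,
    config: dict | None = None,
    extra: dict | None = None,
    index: bool = False,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(seed, config, extra)) + "\n")
        df.to_csv(fh, sep=_sep_for(path), index=index)
    return path


def _read_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    return pd.read_csv(path, sep=_sep_for(path), comment="#")


def read_ct_table(path) -> pd.DataFrame:
    """Read and validate a raw Ct table (CSV or TSV by extension)."""
    table = read_table(path)
    return validate_ct_table(table)


def write_feature_matrix(fm: FeatureMatrix, path, seed=None, config=None) -> Path:
    wide = fm.values.copy()
    wide.insert(0, S.EXPERIENCE, fm.labels)
    return write_table(
        wide.reset_index(),
        path,
        seed=seed,
        config=config,
        extra={"transform": fm.transform},
    )


def read_feature_matrix(path) -> FeatureMatrix:
    meta = _read_header(Path(path))
    df = read_table(path)
    for col in (S.MOUSE, S.EXPERIENCE):
        if col not in df.columns:
            raise SchemaError(f"feature matrix file is missing column {col!r}")
    df = df.set_index(S.MOUSE)
    labels = df.pop(S.EXPERIENCE)
    return FeatureMatrix(
        values=df.astype(float), labels=labels, transform=meta.get("transform", "log2")
    )


def load_config(path) -> dict:
    """Load a YAML pipeline/simulation configuration into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"configuration file {path} must hold a mapping")
    return cfg
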