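"""Stable file dialects, configuration handling, and integrity checks.

Response tables are plain TSV in long format with header
``cell_id  behavior  trial  response`` (trial 1-based, response 0/1).
All pipeline outputs carry the configuration hash as a leading ``#``
comment line so a run directory is self-describing and reruns are
verifiable bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import IntegrityError

RESPONSE_COLUMNS = ["cell_id", "behavior", "trial", "response"]

DEFAULT_CONFIG = {
    "d": 3,
    "isi_s": 10.0,
    "n_trials": 60,
    "prior_a": 1.0,
    "prior_b": 1.0,
    "smoothing": 1.0,
    "dt_mode": "step",  # "step" (one ISI) or "period" (one 3-ISI state)
    "entropy_unit": "JK",  # "JK" or "bits"
    "master_seed": 0,
    "simulate": True,
}


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    """Load a flat key-value YAML config, filling defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise IntegrityError(f"config file {path} is not a flat key-value mapping")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def dump_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, default_flow_style=False, sort_keys=True)


def write_table(df: pd.DataFrame, path: str | Path, cfg_hash: str | None = None) -> None:
    """Write a TSV, optionally stamped with the configuration hash."""
    path = Path(path)
    with open(path, "w") as fh:
        if cfg_hash:
            fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_response_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format response table.

    Checks: required columns present; responses binary; no duplicate
    (cell, behavior, trial); trials contiguous 1..n within each
    cell x behavior.  Rows may arrive in any order; output is sorted by
    (cell_id, behavior, trial).  Unknown columns are preserved.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"response table missing column(s) {missing}")
    bad = ~df["response"].isin([0, 1])
    if bad.any():
        row = int(df.index[bad][0])
        raise IntegrityError(
            f"non-binary response {df.loc[row, 'response']!r} at row {row} "
            f"(cell {df.loc[row, 'cell_id']}, trial {df.loc[row, 'trial']})"
        )
    dup = df.duplicated(subset=["cell_id", "behavior", "trial"])
    if dup.any():
        row = df[dup].iloc[0]
        raise IntegrityError(
            f"duplicate entry for cell {row['cell_id']}, behavior "
            f"{row['behavior']}, trial {row['trial']}"
        )
    df = df.sort_values(["cell_id", "behavior", "trial"]).reset_index(drop=True)
    for (cell, behavior), grp in df.groupby(["cell_id", "behavior"]):
        trials = grp["trial"].to_numpy()
        expected = range(1, len(trials) + 1)
        gaps = [e for e, t in zip(expected, trials) if e != t]
        if gaps:
            raise IntegrityError(
                f"missing or misnumbered trial {gaps[0]} for cell {cell}, "
                f"behavior {behavior}"
            )
    return df
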