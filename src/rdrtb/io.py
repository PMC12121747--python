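"""CSV readers/writers and config parsing.

The on-disk trial schema is the wide CSV ``id, arm, y0..yJ,
withdrawal_visit, rd_flag`` with missing cells written as empty strings
(dialect-neutral, no "NA" sentinel).  Draw stacks are one CSV per
imputation plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .frames import ConfigError, TrialDataError, validate_trial_frame, visit_columns
from .mi import ImputationDraw
from .simulate import SimConfig


def read_trial_csv(path, n_visits: int | None = None, kind: str = "observed") -> pd.DataFrame:
    """Read and validate a trial CSV.

    ``kind``: "observed" requires non-RD withdrawers to be missing from the
    withdrawal visit onward; "truth" requires a fully observed frame; "any"
    only checks the shared invariants.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if "rd_flag" in frame.columns:
        frame["rd_flag"] = frame["rd_flag"].astype(bool)
    if kind == "observed":
        validate_trial_frame(frame, n_visits, require_missing_after_withdrawal=True)
    elif kind == "truth":
        validate_trial_frame(frame, n_visits, allow_missing=False)
    elif kind == "any":
        validate_trial_frame(frame, n_visits)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return frame


def write_trial_csv(frame: pd.DataFrame, path) -> Path:
    """Write a trial frame with empty-string missing cells."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = frame.copy()
    out["rd_flag"] = out["rd_flag"].astype(bool)
    out.to_csv(path, index=False, na_rep="")
    return path


def write_draw_stack(
    draws: list[ImputationDraw],
    out_dir,
    method: str | None = None,
    seed: int | None = None,
    ledger: dict | None = None,
) -> list[Path]:
    """Write one CSV per draw plus ``manifest.json``; returns the paths."""
    if not draws:
        raise ValueError("no draws to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for draw in draws:
        p = out_dir / f"draw_{draw.m:04d}.csv"
        write_trial_csv(draw.frame, p)
        paths.append(p)
    manifest = {
        "n_imputations": len(draws),
        "method": method,
        "seed": seed,
        "files": [p.name for p in paths],
    }
    if ledger is not None:
        manifest["ledger"] = ledger
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths


def read_draw_stack(in_dir) -> list[ImputationDraw]:
    """Re-read a draw stack written by :func:`write_draw_stack`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    draws = []
    for m, name in enumerate(manifest["files"]):
        frame = read_trial_csv(in_dir / name, kind="any")
        cols = visit_columns(validate_trial_frame(frame))
        if frame[cols].isna().any().any():
            raise TrialDataError(f"draw file {name} has missing cells")
        draws.append(ImputationDraw(frame, np.zeros(frame[cols].shape, dtype=bool), m))
    return draws


_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def load_sim_config(path) -> SimConfig:
    """Load a :class:`SimConfig` from YAML or JSON, rejecting unknown keys."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(data) - _SIM_FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("baseline_range", "withdrawal_visit_weights"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SimConfig(**data)
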