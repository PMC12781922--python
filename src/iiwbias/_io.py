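"""File formats and configuration.

The single interchange format is a long-format visits CSV with header
``subject_id,time,outcome`` -- one row per assessment including a ``time=0``
baseline row for every subject; a subject with only its baseline row is a
zero-follow-up subject.  Counting-process tables
(``subject_id,start,stop,event,z...``) are derived, never hand-authored.
Times are written as full-precision decimal text so write/read round-trips
exactly.  Every CSV written by the CLI starts with provenance comment lines
(config hash, seed) that the readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .intensity import CORE_COLUMNS
from .simulate import OutcomeModelSpec, SubjectPath, VisitModelSpec

__all__ = [
    "read_visits",
    "write_visits",
    "read_counting_process",
    "write_counting_process",
    "load_config",
    "config_hash",
    "specs_from_config",
]

VISIT_COLUMNS = ("subject_id", "time", "outcome")


class ParseError(ValueError):
    """CSV/config validation failure with file / row context."""


def read_visits(path) -> list[SubjectPath]:
    """Read a long-format visits CSV into subject paths.

    Rows are grouped by subject and sorted by time; the ``time=0`` row is the
    baseline (required for every subject) and the remaining rows are
    follow-up assessments.  Duplicate (subject, time) pairs and non-numeric
    fields are rejected with the offending location.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in ("time", "outcome"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric {col!r} at data row {bad[0] + 1}"
            )
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 1
            raise ParseError(f"{path}: missing {col!r} at data row {row}")
        df[col] = vals
    dup = df.duplicated(subset=["subject_id", "time"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate (subject_id, time) = "
            f"({row['subject_id']}, {row['time']})"
        )
    paths: list[SubjectPath] = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("time")
        times = grp["time"].to_numpy(float)
        if times[0] != 0.0:
            raise ParseError(f"{path}: subject {sid} has no time=0 baseline row")
        paths.append(
            SubjectPath(
                subject_id=sid,
                baseline_y=float(grp["outcome"].iloc[0]),
                visit_times=times[1:],
                visit_outcomes=grp["outcome"].to_numpy(float)[1:],
            )
        )
    return paths


def _provenance_header(meta: dict | None) -> str:
    if not meta:
        return ""
    items = ", ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# {items}\n"


def write_visits(paths: list[SubjectPath], path, meta: dict | None = None) -> None:
    """Write subject paths as a long-format visits CSV (full precision)."""
    records = []
    for p in paths:
        records.append((p.subject_id, 0.0, p.baseline_y))
        records.extend(zip([p.subject_id] * p.n_visits, p.visit_times, p.visit_outcomes))
    df = pd.DataFrame(records, columns=list(VISIT_COLUMNS))
    with open(path, "w") as fh:
        fh.write(_provenance_header(meta))
        df.to_csv(fh, index=False)


def read_counting_process(path) -> pd.DataFrame:
    """Read a counting-process CSV (subject_id,start,stop,event,z...)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def write_counting_process(rows: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(meta))
        rows.to_csv(fh, index=False)


# --- configuration -----------------------------------------------------------

_OUTCOME_KEYS = {f.name for f in OutcomeModelSpec.__dataclass_fields__.values()}
_VISIT_KEYS = {"lambda0", "gamma0", "tau"}
_TOP_KEYS = {"outcome", "visit", "n", "seed"}


def load_config(path) -> dict:
    """Load and validate a simulation config (YAML).

    Layout::

        outcome: {mechanism: 1, sigma_u: 1.6, ...}   # OutcomeModelSpec fields
        visit:   {lambda0: 0.5, gamma0: 0.5, tau: 2.0}
        n: 500
        seed: 1

    Unknown keys anywhere are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown top-level keys {sorted(unknown)}")
    for section, allowed in (("outcome", _OUTCOME_KEYS), ("visit", _VISIT_KEYS)):
        sub = cfg.get(section, {})
        if not isinstance(sub, dict):
            raise ParseError(f"{path}: section {section!r} must be a mapping")
        bad = set(sub) - allowed
        if bad:
            raise ParseError(f"{path}: unknown keys in {section!r}: {sorted(bad)}")
    if "n" in cfg and (not isinstance(cfg["n"], int) or cfg["n"] < 1):
        raise ParseError(f"{path}: field 'n' must be a positive integer")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        raise ParseError(f"{path}: field 'seed' must be an integer")
    return cfg


def specs_from_config(cfg: dict):
    """Build (OutcomeModelSpec, VisitModelSpec, n, seed) from a parsed config."""
    outcome = OutcomeModelSpec(**cfg.get("outcome", {}))
    visit = VisitModelSpec(**cfg.get("visit", {}))
    return outcome, visit, int(cfg.get("n", 500)), int(cfg.get("seed", 0))


def config_hash(cfg: dict) -> str:
    """Short stable hash of a config mapping, for output provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
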