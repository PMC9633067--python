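"""Trial-table file schema and dataset adapters.

The canonical on-disk format is delimited text (CSV, UTF-8, decimal
point) with the header::

    participant_id,group,phase,trial,target_deg,error_deg,feedback

one row per trial, degrees of visual angle, rightward positive.  The
adapter maps a deposited dataset with a different layout onto this
schema via a user-supplied column mapping and can convert ruler offsets
in cm to degrees using the viewing distance.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .simulation import GROUPS, PHASES, TRIAL_COLUMNS

__all__ = ["SchemaError", "read_trial_table", "write_trial_table", "adapt_deposited_dataset"]

logger = logging.getLogger("prismadapt")

_BOOL_MAP = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "yes": True,
    "no": False,
}


class SchemaError(ValueError):
    """A trial-table file violates the documented column schema."""


def _coerce_bool(series: pd.Series) -> tuple[pd.Series, list[int]]:
    bad = []
    out = []
    for i, v in enumerate(series):
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
            continue
        key = str(v).strip().lower()
        if key in _BOOL_MAP:
            out.append(_BOOL_MAP[key])
        else:
            out.append(False)
            bad.append(i)
    return pd.Series(out, index=series.index), bad


def _lines(idx) -> str:
    shown = [str(i + 2) for i in list(idx)[:5]]  # +2: header + 1-based
    more = "" if len(idx) <= 5 else f" (+{len(idx) - 5} more)"
    return ", ".join(shown) + more


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a canonical trial table.

    Raises :class:`SchemaError` naming missing columns, unknown enum
    values or non-numeric fields, with 1-based file line numbers.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")

    bad = df.index[~df["group"].isin(GROUPS)]
    if len(bad):
        raise SchemaError(
            f"{path}: unknown group value(s) {sorted(df.loc[bad, 'group'].unique())} "
            f"at line(s) {_lines(bad)}"
        )
    bad = df.index[~df["phase"].isin(PHASES)]
    if len(bad):
        raise SchemaError(
            f"{path}: unknown phase value(s) {sorted(df.loc[bad, 'phase'].unique())} "
            f"at line(s) {_lines(bad)}"
        )
    for col in ("trial", "target_deg", "error_deg"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric {col!r} at line(s) {_lines(bad)}"
            )
        df[col] = coerced
    trial = df["trial"]
    bad = df.index[(trial < 1) | (trial != trial.round())]
    if len(bad):
        raise SchemaError(f"{path}: trial indices must be integers >= 1 at line(s) {_lines(bad)}")
    df["trial"] = df["trial"].astype(int)
    df["feedback"], bad = _coerce_bool(df["feedback"])
    if bad:
        raise SchemaError(f"{path}: non-boolean 'feedback' at line(s) {_lines(bad)}")
    return df[TRIAL_COLUMNS]


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"table missing column(s): {', '.join(missing)}")
    table[TRIAL_COLUMNS].to_csv(path, index=False)


METADATA_COLUMNS = ("time_since_surgery_years", "age_years", "acuity_cpd")


def adapt_deposited_dataset(path, mapping: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalise a deposited dataset onto the canonical trial schema.

    ``mapping`` is a dict with:

    ``columns``
        ``{canonical_name: source_column}`` for the seven trial columns;
        an identity mapping on an already-canonical file reproduces
        :func:`read_trial_table`.
    ``group_map`` (optional)
        source group labels -> canonical ``cataract/control/control_blur``.
    ``position`` (optional)
        ``{"unit": "cm", "viewing_distance_cm": d}``: pointing offsets on
        the recording ruler are converted per row with
        ``error_deg = degrees(atan(offset_cm / d))``.
    ``metadata`` (optional)
        ``{canonical: source}`` for per-participant fields
        (``time_since_surgery_years``, ``age_years``, ``acuity_cpd``).

    Returns ``(trial_table, participants)``; ``participants`` has one row
    per participant with whatever metadata was mapped.  A cataract
    participant lacking time since surgery triggers a warning (the
    development fit excludes them; nothing else does).
    """
    raw = pd.read_csv(path)
    colmap = mapping.get("columns", {})
    missing = [c for c in TRIAL_COLUMNS if c not in colmap]
    if missing:
        raise SchemaError(
            f"mapping incomplete: no source column for {', '.join(missing)}"
        )
    absent = [src for src in colmap.values() if src not in raw.columns]
    if absent:
        raise SchemaError(f"{path}: mapped source column(s) not found: {', '.join(absent)}")

    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})
    df["participant_id"] = df["participant_id"].astype(str)
    group_map = mapping.get("group_map")
    if group_map:
        df["group"] = df["group"].map(lambda g: group_map.get(g, g))
    position = mapping.get("position")
    if position and position.get("unit", "deg") == "cm":
        d = float(position["viewing_distance_cm"])
        if d <= 0:
            raise ValueError("viewing_distance_cm must be positive")
        df["error_deg"] = np.degrees(np.arctan(df["error_deg"].astype(float) / d))

    used = set(colmap.values()) | set((mapping.get("metadata") or {}).values())
    unmapped = [c for c in raw.columns if c not in used]
    if unmapped:
        logger.info("adapter: unmapped source columns ignored: %s", ", ".join(unmapped))

    meta_map = mapping.get("metadata") or {}
    meta_cols = {"participant_id": df["participant_id"]}
    participants = df[["participant_id", "group"]].drop_duplicates("participant_id")
    for canon, src in meta_map.items():
        if src not in raw.columns:
            raise SchemaError(f"{path}: metadata column {src!r} not found")
        per = (
            pd.DataFrame({"participant_id": df["participant_id"], canon: raw[src]})
            .drop_duplicates("participant_id")
        )
        participants = participants.merge(per, on="participant_id", how="left")

    if "time_since_surgery_years" in participants.columns:
        cataract = participants[participants["group"] == "cataract"]
        no_time = cataract[cataract["time_since_surgery_years"].isna()]
        if len(no_time):
            warnings.warn(
                "missing time_since_surgery_years for cataract participant(s) "
                f"{sorted(no_time['participant_id'])}; they are excluded from the "
                "development fit only",
                stacklevel=2,
            )

    table = df[TRIAL_COLUMNS].copy()
    table["trial"] = pd.to_numeric(table["trial"]).astype(int)
    table["target_deg"] = pd.to_numeric(table["target_deg"]).astype(float)
    table["error_deg"] = pd.to_numeric(table["error_deg"]).astype(float)
    table["feedback"], bad = _coerce_bool(table["feedback"])
    if bad:
        raise SchemaError(f"{path}: non-boolean feedback values after mapping")
    unknown = set(table["group"]) - set(GROUPS)
    if unknown:
        raise SchemaError(f"{path}: unmapped group label(s): {sorted(unknown)}")
    unknown = set(table["phase"]) - set(PHASES)
    if unknown:
        raise SchemaError(f"{path}: unmapped phase label(s): {sorted(unknown)}")
    return table, participants
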