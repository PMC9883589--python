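"""Delimited-text I/O with schema validation.

All tables are plain CSV. Reaction times are stored as integer
milliseconds (``rt_ms``, blank when there was no response) and converted
to float seconds in memory, so write-then-read round-trips are bit-exact.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = [
    "TableValidationError",
    "read_trials", "write_trials",
    "read_sessions", "write_sessions",
    "read_events", "write_events",
]

_VALID_STIM = {"target", "identity_foil", "location_foil"}
_VALID_SESSION = {"T1", "T2", "T3"}
_VALID_EVENT = {"asa", "aborted", "interrupted", "preparatory",
                "si_admission", "study_end", "withdrawal", "death"}


class TableValidationError(ValueError):
    """A table violates its schema; the message names row and column."""


def _read_csv(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise TableValidationError(f"{path}: file is empty")
    df = pd.read_csv(path)
    if len(df) == 0:
        raise TableValidationError(f"{path}: no data rows")
    return df

def _require(df, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing columns {missing}")


def write_trials(trials: pd.DataFrame, path) -> None:
    out = trials.copy()
    rt_ms = np.round(out["rt"].astype(float) * 1000)
    out["rt_ms"] = pd.array(
        np.where(out["responded"].astype(bool), rt_ms, np.nan), dtype="Int64")
    out["responded"] = out["responded"].astype(int)
    cols = ["participant_id", "session_label", "trial_index", "letter",
            "row", "position", "stim_class", "responded", "rt_ms"]
    out[cols].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trials table; returns RTs in seconds."""
    df = _read_csv(path)
    cols = ["participant_id", "session_label", "trial_index", "letter",
            "row", "position", "stim_class", "responded", "rt_ms"]
    _require(df, cols, path)
    responded = df["responded"].astype(int)
    has_rt = df["rt_ms"].notna()
    for idx in df.index[(responded == 0) & has_rt]:
        raise TableValidationError(
            f"{path} row {idx + 2}: rt_ms present but responded=0")
    for idx in df.index[(responded == 1) & ~has_rt]:
        raise TableValidationError(
            f"{path} row {idx + 2}: responded=1 but rt_ms blank")
    bad = ~df["stim_class"].isin(_VALID_STIM)
    if bad.any():
        idx = df.index[bad][0]
        raise TableValidationError(
            f"{path} row {idx + 2}: bad stim_class {df.loc[idx, 'stim_class']!r}")
    expect = np.where(df["row"] == "lower", "location_foil",
                      np.where(df["letter"] == "X", "target", "identity_foil"))
    bad = df["stim_class"].to_numpy() != expect
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise TableValidationError(
            f"{path} row {idx + 2}: stim_class inconsistent with letter/row")
    rt_ms = df["rt_ms"].astype("Int64")
    if ((rt_ms <= 0) & has_rt).any():
        idx = df.index[(rt_ms <= 0).fillna(False)][0]
        raise TableValidationError(f"{path} row {idx + 2}: rt_ms must be > 0")
    out = df.copy()
    out["responded"] = responded.astype(bool)
    out["rt"] = rt_ms.astype(float) / 1000.0
    return out.drop(columns=["rt_ms"])


def write_sessions(sessions: pd.DataFrame, path) -> None:
    sessions.to_csv(path, index=False)


def read_sessions(path) -> pd.DataFrame:
    df = _read_csv(path)
    cols = ["participant_id", "session_label", "test_day", "age", "gender",
            "ssi", "lifetime_asa_count", "tbi", "treatment_arm", "stroop_d"]
    _require(df, cols, path)
    bad = ~df["session_label"].isin(_VALID_SESSION)
    if bad.any():
        idx = df.index[bad][0]
        raise TableValidationError(
            f"{path} row {idx + 2}: bad session_label "
            f"{df.loc[idx, 'session_label']!r}")
    if (df["test_day"].astype(int) < 0).any():
        idx = df.index[df["test_day"].astype(int) < 0][0]
        raise TableValidationError(f"{path} row {idx + 2}: negative test_day")
    dup = df.duplicated(["participant_id", "session_label"])
    if dup.any():
        idx = df.index[dup][0]
        raise TableValidationError(
            f"{path} row {idx + 2}: duplicate participant/session")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, ["participant_id", "event_day", "event_type"], path)
    bad = ~df["event_type"].isin(_VALID_EVENT)
    if bad.any():
        idx = df.index[bad][0]
        raise TableValidationError(
            f"{path} row {idx + 2}: bad event_type {df.loc[idx, 'event_type']!r}")
    if (df["event_day"].astype(int) < 0).any():
        idx = df.index[df["event_day"].astype(int) < 0][0]
        raise TableValidationError(f"{path} row {idx + 2}: negative event_day")
    terminal = df[df["event_type"].isin({"study_end", "withdrawal", "death"})]
    dup = terminal.duplicated("participant_id")
    if dup.any():
        pid = terminal.loc[dup.index[dup][0], "participant_id"]
        raise TableValidationError(
            f"{path}: participant {pid} has multiple terminal records")
    return df
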