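"""Prospective 90-day outcome labeling from clinical event logs.

Each testing session is labeled with exactly one of three mutually
exclusive categories based on the 90 days after testing:

* ``ASA`` — at least one actual suicide attempt in the window;
* ``OtherSE`` — no attempt, but at least one other suicide-related event
  (aborted or interrupted attempt, preparatory behavior, or a
  suicide-ideation-related hospital admission);
* ``noSE`` — neither, with the window fully observed.

Windows truncated by study end, withdrawal, or death before day 90 with no
qualifying event are ``censored`` and excluded from modeling. An event
observed before the censoring date still labels the window (event
precedence). The window is half-open, ``(test_day, test_day + horizon]``:
same-day events are not "subsequent" to testing; day-90 events are in.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ASA_TYPES",
    "OTHER_SE_TYPES",
    "CENSORING_TYPES",
    "OutcomeLabel",
    "classify_window",
    "label_all",
]

ASA_TYPES = frozenset({"asa"})
OTHER_SE_TYPES = frozenset({"aborted", "interrupted", "preparatory",
                            "si_admission"})
CENSORING_TYPES = frozenset({"study_end", "withdrawal", "death"})
EVENT_TYPES = ASA_TYPES | OTHER_SE_TYPES | CENSORING_TYPES

DEFAULT_HORIZON = 90
DEFAULT_STUDY_LENGTH = 365


@dataclass(frozen=True)
class OutcomeLabel:
    participant_id: str
    session_label: str
    category: str               # ASA | OtherSE | noSE | censored
    first_event_day: int | None


def classify_window(test_day: int, events: pd.DataFrame,
                    horizon: int = DEFAULT_HORIZON,
                    study_length: int = DEFAULT_STUDY_LENGTH,
                    participant_id: str | None = None) -> tuple[str, int | None]:
    """Classify one session's window; returns ``(category, first_event_day)``.

    ``events`` holds one participant's records (columns ``event_day``,
    ``event_type``, optionally ``participant_id``). A participant with no
    terminal record is assumed observed through ``study_length``.
    """
    if test_day < 0:
        raise ValueError("test_day must be >= 0")
    if participant_id is not None and "participant_id" in events.columns:
        other = set(events["participant_id"]) - {participant_id}
        if other:
            raise ValueError(f"events for foreign participants: {sorted(other)}")
    unknown = set(events["event_type"]) - EVENT_TYPES
    if unknown:
        raise ValueError(f"unknown event types: {sorted(unknown)}")

    lo, hi = test_day, test_day + horizon
    day = events["event_day"].astype(int)
    in_window = (day > lo) & (day <= hi)
    etype = events["event_type"]

    asa_days = day[in_window & etype.isin(ASA_TYPES)]
    if len(asa_days):
        return "ASA", int(asa_days.min())
    other_days = day[in_window & etype.isin(OTHER_SE_TYPES)]
    if len(other_days):
        return "OtherSE", int(other_days.min())

    terminal = day[etype.isin(CENSORING_TYPES)]
    observed_through = int(terminal.min()) if len(terminal) else study_length
    if observed_through >= hi:
        return "noSE", None
    return "censored", None


def label_all(sessions: pd.DataFrame, events: pd.DataFrame,
              horizon: int = DEFAULT_HORIZON,
              study_length: int = DEFAULT_STUDY_LENGTH) -> pd.DataFrame:
    """One outcome label per session row.

    The same event may label two sessions whose windows both contain it.
    Participants absent from the event table are treated as fully observed
    through ``study_length`` (no terminal record means no censoring).
    """
    if "test_day" not in sessions.columns:
        raise ValueError("sessions table must carry test_day")
    by_pid = dict(tuple(events.groupby("participant_id"))) if len(events) else {}
    empty = events.iloc[0:0]
    rows = []
    for rec in sessions.itertuples(index=False):
        ev = by_pid.get(rec.participant_id, empty)
        cat, first_day = classify_window(int(rec.test_day), ev, horizon,
                                         study_length)
        rows.append((rec.participant_id, rec.session_label, cat, first_day))
    out = pd.DataFrame(rows, columns=["participant_id", "session_label",
                                      "category", "first_event_day"])
    out["first_event_day"] = out["first_event_day"].astype("Int64")
    return out
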