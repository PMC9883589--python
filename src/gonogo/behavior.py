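"""Observable Go/No-go and Stroop variables, plus data-cleansing flags.

Scoring conventions: a Go response to a target is a hit, withholding is a
miss (omission error); a Go response to a foil is a false alarm (commission
error), withholding is a correct withhold. Responses faster than 200 ms are
discarded as anticipatory, responses slower than 1 s as reflecting
inattention; a trial whose only response was discarded this way is excluded
from both numerator and denominator of the percentage scores (the filter
drops *responses*, not trials, and counting an anticipatory press as a miss
would conflate two different behaviors). Set ``drop_filtered_trials=False``
in :func:`score_session` to score such trials as non-responses instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BehavioralSummary",
    "StroopSummary",
    "ScoringError",
    "filter_rts",
    "score_session",
    "score_all",
    "stroop_dscore",
    "compliance_flags",
]

RT_LOW = 0.2   # seconds; responses strictly below are anticipatory
RT_HIGH = 1.0  # seconds; responses strictly above reflect inattention

FOIL_CLASSES = ("identity_foil", "location_foil")


class ScoringError(ValueError):
    """A session cannot be scored (empty or too-small category)."""


@dataclass(frozen=True)
class BehavioralSummary:
    pct_misses: float
    pct_false_alarms: float
    pct_fa_identity: float
    pct_fa_location: float
    mean_hit_rt: float
    n_dropped_short: int
    n_dropped_long: int
    n_trials_scored: int
    n_targets_scored: int
    n_foils_scored: int
    n_false_alarms: int


@dataclass(frozen=True)
class StroopSummary:
    d_score: float
    mean_rt_congruent: float
    mean_rt_incongruent: float


def filter_rts(trials: pd.DataFrame, low: float = RT_LOW,
               high: float = RT_HIGH) -> tuple[pd.DataFrame, int, int]:
    """Remove anticipatory (< ``low``) and slow (> ``high``) responses.

    Boundary values are retained (strict inequalities). The trial row is
    kept with ``responded`` cleared and an ``rt_dropped`` marker of
    ``"short"`` or ``"long"``; idempotent on already-filtered data.
    Returns ``(filtered, n_dropped_short, n_dropped_long)``.
    """
    if not low < high:
        raise ValueError("need low < high")
    out = trials.copy()
    if "rt_dropped" not in out.columns:
        out["rt_dropped"] = pd.Series(pd.NA, index=out.index, dtype="object")
    responded = out["responded"].astype(bool)
    rt = out["rt"].astype(float)
    short = responded & (rt < low)
    long_ = responded & (rt > high)
    out.loc[short, "rt_dropped"] = "short"
    out.loc[long_, "rt_dropped"] = "long"
    out.loc[short | long_, "responded"] = False
    out.loc[short | long_, "rt"] = np.nan
    return out, int(short.sum()), int(long_.sum())


def _scored_mask(trials: pd.DataFrame, drop_filtered_trials: bool) -> pd.Series:
    if drop_filtered_trials and "rt_dropped" in trials.columns:
        return trials["rt_dropped"].isna()
    return pd.Series(True, index=trials.index)


def score_session(trials: pd.DataFrame, *, drop_filtered_trials: bool = True,
                  min_targets: int = 20, min_foils: int = 10) -> BehavioralSummary:
    """Percent misses / false alarms (overall and per foil subtype) for one
    RT-filtered session.

    Truncated sessions are scored over whatever trials were recorded, but at
    least ``min_targets`` scored targets and ``min_foils`` scored foils are
    required — refusing to summarize a nearly-empty file beats emitting a
    percentage computed over a handful of trials.
    """
    scored = trials[_scored_mask(trials, drop_filtered_trials)]
    is_target = scored["stim_class"] == "target"
    targets = scored[is_target]
    foils = scored[~is_target]
    if len(targets) < max(min_targets, 1) or len(foils) < max(min_foils, 1):
        raise ScoringError(
            f"too few scored trials ({len(targets)} targets, {len(foils)} foils); "
            f"need >= {min_targets} targets and >= {min_foils} foils"
        )
    n_short = int((trials.get("rt_dropped") == "short").sum()) if "rt_dropped" in trials.columns else 0
    n_long = int((trials.get("rt_dropped") == "long").sum()) if "rt_dropped" in trials.columns else 0

    t_resp = targets["responded"].astype(bool)
    f_resp = foils["responded"].astype(bool)
    identity = foils[foils["stim_class"] == "identity_foil"]
    location = foils[foils["stim_class"] == "location_foil"]

    def pct(num, den):
        return 100.0 * num / den if den else float("nan")

    hit_rts = targets.loc[t_resp, "rt"].astype(float)
    return BehavioralSummary(
        pct_misses=pct((~t_resp).sum(), len(targets)),
        pct_false_alarms=pct(f_resp.sum(), len(foils)),
        pct_fa_identity=pct(identity["responded"].astype(bool).sum(), len(identity)),
        pct_fa_location=pct(location["responded"].astype(bool).sum(), len(location)),
        mean_hit_rt=float(hit_rts.mean()) if len(hit_rts) else float("nan"),
        n_dropped_short=n_short,
        n_dropped_long=n_long,
        n_trials_scored=len(scored),
        n_targets_scored=len(targets),
        n_foils_scored=len(foils),
        n_false_alarms=int(f_resp.sum()),
    )


def score_all(trials: pd.DataFrame, *, drop_filtered_trials: bool = True,
              min_targets: int = 20, min_foils: int = 10) -> pd.DataFrame:
    """Vectorized per-session scoring of a multi-session trial table.

    Returns one row per (participant_id, session_label) with the same
    quantities as :class:`BehavioralSummary`. Sessions failing the minimum
    trial counts are omitted (they cannot be scored).
    """
    df = pd.DataFrame({
        "participant_id": trials["participant_id"].to_numpy(),
        "session_label": trials["session_label"].to_numpy(),
    })
    scored = _scored_mask(trials, drop_filtered_trials).to_numpy()
    resp = trials["responded"].astype(bool).to_numpy() & scored
    cls = trials["stim_class"].to_numpy()
    is_target = cls == "target"
    is_ident = cls == "identity_foil"
    is_loc = cls == "location_foil"
    rt = trials["rt"].to_numpy(dtype=float)
    if "rt_dropped" in trials.columns:
        dropped = trials["rt_dropped"]
        df["n_dropped_short"] = (dropped == "short").fillna(False).to_numpy()
        df["n_dropped_long"] = (dropped == "long").fillna(False).to_numpy()
    else:
        df["n_dropped_short"] = False
        df["n_dropped_long"] = False
    df["n_targets_scored"] = scored & is_target
    df["n_foils_scored"] = scored & ~is_target
    df["n_hits"] = resp & is_target
    df["n_false_alarms"] = resp & ~is_target
    df["_n_ident"] = scored & is_ident
    df["_fa_ident"] = resp & is_ident
    df["_n_loc"] = scored & is_loc
    df["_fa_loc"] = resp & is_loc
    df["_hit_rt_sum"] = np.where(resp & is_target, rt, 0.0)

    out = df.groupby(["participant_id", "session_label"], sort=True,
                     observed=True).sum()
    out = out[(out["n_targets_scored"] >= max(min_targets, 1))
              & (out["n_foils_scored"] >= max(min_foils, 1))]
    out["pct_misses"] = 100.0 * (1 - out["n_hits"] / out["n_targets_scored"])
    out["pct_false_alarms"] = 100.0 * out["n_false_alarms"] / out["n_foils_scored"]
    with np.errstate(invalid="ignore"):
        out["pct_fa_identity"] = 100.0 * out["_fa_ident"] / out["_n_ident"]
        out["pct_fa_location"] = 100.0 * out["_fa_loc"] / out["_n_loc"]
        out["mean_hit_rt"] = out["_hit_rt_sum"] / out["n_hits"]
    out["n_trials_scored"] = out["n_targets_scored"] + out["n_foils_scored"]
    return (out.drop(columns=[c for c in out.columns if c.startswith("_")])
            .reset_index())


def stroop_dscore(stroop_trials: pd.DataFrame) -> StroopSummary:
    """Interference d-score: (mean incongruent RT - mean congruent RT) /
    mean congruent RT. Higher values mean greater interference (poorer
    attentional control). All trials count — the stimulus stays on screen
    until the correct response, so every RT is a correct-response RT.
    """
    cong = stroop_trials.loc[stroop_trials["congruent"].astype(bool), "rt"].astype(float)
    incong = stroop_trials.loc[~stroop_trials["congruent"].astype(bool), "rt"].astype(float)
    if len(cong) == 0 or len(incong) == 0:
        raise ScoringError("need at least one trial of each congruency")
    mc, mi = float(cong.mean()), float(incong.mean())
    if mc == 0:
        raise ScoringError("zero mean congruent RT")
    return StroopSummary(d_score=(mi - mc) / mc,
                         mean_rt_congruent=mc, mean_rt_incongruent=mi)


def compliance_flags(trials: pd.DataFrame) -> set[str]:
    """Noncompliance screens applied per session.

    ``no_go_responses``: the participant never pressed the key anywhere in
    the session (possibly pressing a wrong key). ``single_foil_errors``:
    90-100% false alarms on exactly one foil subtype (the requirement to
    inhibit to *both* foil types was likely misunderstood). Assessed on the
    retained (post-filter) responses when a filtered table is passed.
    """
    flags: set[str] = set()
    if "rt_dropped" in trials.columns:
        scored = trials[trials["rt_dropped"].isna()]
    else:
        scored = trials
    if not scored["responded"].astype(bool).any():
        flags.add("no_go_responses")
        return flags
    rates = {}
    for cls in FOIL_CLASSES:
        sub = scored[scored["stim_class"] == cls]
        if len(sub):
            rates[cls] = 100.0 * sub["responded"].astype(bool).mean()
    if len(rates) == 2:
        high = [c for c, r in rates.items() if r >= 90.0]
        if len(high) == 1:
            flags.add("single_foil_errors")
    return flags
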