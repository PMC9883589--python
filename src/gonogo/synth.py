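"""Synthetic Go/No-go cohorts with planted group effects.

The generator reproduces the structure of the task and study design that
the downstream analysis assumes:

* each session presents 225 trials — 144 targets (X in the upper screen
  half), 36 identity foils (Y upper), and 45 location foils (36 X and 9 Y
  in the lower half) — with a 300 ms stimulus followed by a 1200 ms blank
  (1.5 s trials);
* behavior on each trial comes from a two-accumulator LBA race with
  session-level parameters drawn around latent-group means;
* each participant contributes up to three sessions (T1/T2/T3, 90 days
  apart) and an event history that places suicide attempts and other
  suicide-related events in the 90-day windows after testing at
  group-dependent rates.

Three latent groups plant the effects the analysis should recover: an
"ASA-like" group with reduced decisional efficiency for targets (raising
misses), an "OtherSE-like" group with a larger Go response bias
``B_nogo - B_go`` (raising false alarms), and a "noSE-like" majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lba import LBAParams, FREE_PARAM_NAMES

__all__ = [
    "STIMULUS_DURATION",
    "BLANK_DURATION",
    "TRIAL_LENGTH",
    "SessionSchedule",
    "CohortConfig",
    "generate_schedule",
    "simulate_session",
    "simulate_trials_vectorized",
    "generate_cohort",
    "generate_stroop",
    "generate_noncompliant_session",
    "GROUPS",
    "default_group_means",
]

STIMULUS_DURATION = 0.3   # seconds the letter is visible
BLANK_DURATION = 1.2      # seconds of blank screen after it
TRIAL_LENGTH = STIMULUS_DURATION + BLANK_DURATION

N_TRIALS = 225
N_TARGETS = 144
N_IDENTITY_FOILS = 36
N_LOCATION_FOILS_X = 36
N_LOCATION_FOILS_Y = 9

GROUPS = ("ASA-like", "OtherSE-like", "noSE-like")
SESSION_LABELS = ("T1", "T2", "T3")
SESSION_SPACING_DAYS = 90
OTHER_EVENT_TYPES = ("aborted", "interrupted", "preparatory", "si_admission")


@dataclass(frozen=True)
class SessionSchedule:
    """An ordered 225-trial stimulus sequence plus the display timings."""

    trials: pd.DataFrame  # trial_index, letter, row, position, stim_class
    stimulus_duration: float = STIMULUS_DURATION
    blank_duration: float = BLANK_DURATION

    def __len__(self) -> int:
        return len(self.trials)


def _composition() -> pd.DataFrame:
    """The fixed stimulus composition before ordering."""
    rows = (
        [("X", "upper", "target")] * N_TARGETS
        + [("Y", "upper", "identity_foil")] * N_IDENTITY_FOILS
        + [("X", "lower", "location_foil")] * N_LOCATION_FOILS_X
        + [("Y", "lower", "location_foil")] * N_LOCATION_FOILS_Y
    )
    return pd.DataFrame(rows, columns=["letter", "row", "stim_class"])


def generate_schedule(seed: int) -> SessionSchedule:
    """A seeded session schedule: uniform random trial order, uniform
    positions in {1, 2, 3}, exact composition (144/36/45 with 36 X and 9 Y
    location foils)."""
    rng = np.random.default_rng(seed)
    df = _composition()
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    df.insert(0, "trial_index", np.arange(len(df)))
    df["position"] = rng.integers(1, 4, size=len(df))
    return SessionSchedule(trials=df)


def simulate_trials_vectorized(stim_class: np.ndarray, t0, A, b_go, b_nogo,
                               v_go_target, v_nogo_target, v_go_foil,
                               v_nogo_foil, s, deadline: float,
                               rng: np.random.Generator):
    """Race all trials at once; parameters may be per-trial arrays.

    Returns ``(responded, rt)``: a Go response is recorded iff the Go
    accumulator crosses first *and* ``t0 + decision time <= deadline``;
    the RT includes non-decision time.
    """
    n = stim_class.shape[0]
    is_target = stim_class == "target"
    v_go = np.where(is_target, v_go_target, v_go_foil)
    v_nogo = np.where(is_target, v_nogo_target, v_nogo_foil)
    start_go = rng.uniform(0.0, 1.0, n) * A
    start_nogo = rng.uniform(0.0, 1.0, n) * A
    slope_go = rng.normal(v_go, s)
    slope_nogo = rng.normal(v_nogo, s)
    with np.errstate(divide="ignore"):
        t_go = np.where(slope_go > 0, (b_go - start_go) / slope_go, np.inf)
        t_nogo = np.where(slope_nogo > 0, (b_nogo - start_nogo) / slope_nogo, np.inf)
    rt = t0 + t_go
    responded = (t_go < t_nogo) & (rt <= deadline)
    rt = np.where(responded, rt, np.nan)
    return responded, rt


def simulate_session(schedule: SessionSchedule, params: LBAParams,
                     deadline: float = TRIAL_LENGTH,
                     rng_seed: int = 0) -> pd.DataFrame:
    """Simulate one participant-session under the LBA agent.

    The deadline is the full 1.5 s trial length by default; slow responses
    (RT > 1 s) are removed later by the behavioral filter, mirroring the
    two-stage cleaning of real data.
    """
    if deadline <= 0:
        raise ValueError("deadline must be > 0")
    rng = np.random.default_rng(rng_seed)
    df = schedule.trials.copy()
    responded, rt = simulate_trials_vectorized(
        df["stim_class"].to_numpy(), params.t0, params.A, params.b_go,
        params.b_nogo, params.v_target_go, params.v_target_nogo,
        params.v_foil_go, params.v_foil_nogo, params.s, deadline, rng,
    )
    df["responded"] = responded
    df["rt"] = rt
    return df


def default_group_means() -> dict[str, LBAParams]:
    """Group-level LBA means planting the study's behavioral pattern.

    The baseline produces ~4% misses and ~8% false alarms; the ASA-like
    group lowers the target-Go drift (decisional efficiency for targets
    drops from 2.2 to 1.3, misses rise by ~13 points); the OtherSE-like
    group widens ``B_nogo - B_go`` (Go bias 33 vs 15, false alarms rise by
    ~6 points).
    """
    base = LBAParams(t0=0.25, A=0.35, B_go=0.45, B_nogo=0.60,
                     v_target_go=2.8, v_target_nogo=0.6,
                     v_foil_go=0.3, v_foil_nogo=2.6)
    return {
        "noSE-like": base,
        "ASA-like": replace(base, v_target_go=1.9),
        "OtherSE-like": replace(base, B_go=0.33, B_nogo=0.66),
    }


def _default_param_sd() -> dict[str, float]:
    return {"t0": 0.02, "A": 0.05, "B_go": 0.05, "B_nogo": 0.05,
            "v_target_go": 0.15, "v_target_nogo": 0.15,
            "v_foil_go": 0.15, "v_foil_nogo": 0.15}


def _default_event_rates() -> dict[str, dict[str, float]]:
    # P(attempt) / P(other suicide-related event) per 90-day window
    return {
        "ASA-like": {"asa": 0.5, "other": 0.10},
        "OtherSE-like": {"asa": 0.02, "other": 0.5},
        "noSE-like": {"asa": 0.01, "other": 0.03},
    }


def _default_covariates() -> dict[str, float]:
    return {
        "age_mean": 49.0, "age_sd": 12.0,
        "female_prop": 0.13,
        "ssi_mean": 8.0, "ssi_sd": 6.0,
        "ssi_shift_asa_like": 3.0,    # explicit coupling: SSI higher in ASA-like
        "lifetime_asa_rate": 1.2,     # Poisson mean
        "tbi_prop": 0.35,
        "treatment_prop": 0.5,
        "stroop_base_rt": 0.6,
        "stroop_interference_mean": 0.12,
        "stroop_interference_sd": 0.08,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to regenerate a cohort bit-for-bit."""

    n_participants: int = 100
    sessions_per_participant: int = 2
    group_proportions: dict = field(default_factory=lambda: {
        "ASA-like": 0.10, "OtherSE-like": 0.15, "noSE-like": 0.75})
    group_param_means: dict = field(default_factory=default_group_means)
    param_sd: dict = field(default_factory=_default_param_sd)
    event_rates: dict = field(default_factory=_default_event_rates)
    covariate_distributions: dict = field(default_factory=_default_covariates)
    withdrawal_prob: float = 0.05
    study_length_days: int = 365
    allow_multiple_attempts: bool = False
    deadline: float = TRIAL_LENGTH
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.sessions_per_participant not in (1, 2, 3):
            raise ValueError("sessions_per_participant must be in {1,2,3}")
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        for g, p in self.group_param_means.items():
            if not isinstance(p, LBAParams):
                raise ValueError(f"group mean for {g} must be LBAParams")


def generate_cohort(config: CohortConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (trials, sessions, events) tables for a full cohort.

    Deterministic given ``config.seed``. Each participant gets a latent
    group, per-session LBA parameters around the group means, covariates,
    and an event history whose 90-day post-test windows contain an attempt
    (or other suicide-related event) with the group's rates. All draws are
    vectorized across sessions so large calibration cohorts stay cheap.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    spp = config.sessions_per_participant
    S = n * spp
    groups = list(config.group_proportions)
    probs = np.array([config.group_proportions[g] for g in groups])
    assign = rng.choice(len(groups), size=n, p=probs)       # per participant
    cov = config.covariate_distributions

    pids = np.array([f"P{i:04d}" for i in range(n)])
    sess_pid = np.repeat(np.arange(n), spp)                 # session -> participant
    sess_label = np.tile(np.array(SESSION_LABELS[:spp]), n)
    sess_group = assign[sess_pid]
    test_day = np.tile(np.arange(spp) * SESSION_SPACING_DAYS, n)

    # per-session LBA parameters around the group means
    pvals = {}
    for name in FREE_PARAM_NAMES:
        means = np.array([getattr(config.group_param_means[g], name)
                          for g in groups])[sess_group]
        v = rng.normal(means, config.param_sd.get(name, 0.0))
        if name == "t0":
            v = np.maximum(v, 0.05)
        elif name == "A":
            v = np.maximum(v, 0.0)
        elif name.startswith("B_"):
            v = np.maximum(v, 0.01)
        pvals[name] = v
    s_fixed = config.group_param_means[groups[0]].s

    # schedules: per-session permutation of the fixed composition
    comp = _composition()
    cls_t = comp["stim_class"].to_numpy()
    let_t = comp["letter"].to_numpy()
    row_t = comp["row"].to_numpy()
    perm = rng.permuted(np.tile(np.arange(N_TRIALS), (S, 1)), axis=1)
    stim_class = cls_t[perm].ravel()
    letter = let_t[perm].ravel()
    row = row_t[perm].ravel()
    position = rng.integers(1, 4, size=S * N_TRIALS)

    per_trial = lambda a: np.repeat(a, N_TRIALS)
    responded, rt = simulate_trials_vectorized(
        stim_class, per_trial(pvals["t0"]),
        per_trial(pvals["A"]),
        per_trial(pvals["A"] + pvals["B_go"]),
        per_trial(pvals["A"] + pvals["B_nogo"]),
        per_trial(pvals["v_target_go"]), per_trial(pvals["v_target_nogo"]),
        per_trial(pvals["v_foil_go"]), per_trial(pvals["v_foil_nogo"]),
        s_fixed, config.deadline, rng,
    )
    trials_df = pd.DataFrame({
        "participant_id": per_trial(pids[sess_pid]),
        "session_label": per_trial(sess_label),
        "trial_index": np.tile(np.arange(N_TRIALS), S),
        "letter": letter,
        "row": row,
        "position": position,
        "stim_class": stim_class,
        "responded": responded,
        "rt": rt,
    })

    # covariates (participant-level except SSI and the Stroop jitter)
    age = np.clip(rng.normal(cov["age_mean"], cov["age_sd"], n), 20, 85)
    female = (rng.uniform(size=n) < cov["female_prop"]).astype(int)
    lifetime_asa = rng.poisson(cov["lifetime_asa_rate"], n)
    tbi = (rng.uniform(size=n) < cov["tbi_prop"]).astype(int)
    treatment = (rng.uniform(size=n) < cov["treatment_prop"]).astype(int)
    interference = np.maximum(
        rng.normal(cov["stroop_interference_mean"],
                   cov["stroop_interference_sd"], n), 0.0)
    asa_like = np.array([g == "ASA-like" for g in groups])[sess_group]
    ssi_mean = cov["ssi_mean"] + cov["ssi_shift_asa_like"] * asa_like
    ssi = np.maximum(rng.normal(ssi_mean, cov["ssi_sd"], S), 0.0)
    stroop_d = ((1 + interference[sess_pid])
                * (1 + rng.normal(0, 0.02, S)) - 1.0)

    sessions_df = pd.DataFrame({
        "participant_id": pids[sess_pid],
        "session_label": sess_label,
        "latent_group": np.array(groups)[sess_group],  # ground truth, not a model input
        "test_day": test_day,
        "age": age[sess_pid],
        "gender": female[sess_pid],
        "ssi": ssi,
        "lifetime_asa_count": lifetime_asa[sess_pid],
        "tbi": tbi[sess_pid],
        "treatment_arm": treatment[sess_pid],
        "stroop_d": stroop_d,
    })

    # events: withdrawal (censoring) plus per-window attempts / other SEs
    withdrew = rng.uniform(size=n) < config.withdrawal_prob
    withdraw_day = rng.integers(30, config.study_length_days, size=n)
    obs_end = np.where(withdrew, withdraw_day, config.study_length_days)

    rate_asa = np.array([config.event_rates[g]["asa"] for g in groups])
    rate_other = np.array([config.event_rates[g]["other"] for g in groups])
    asa_hit = rng.uniform(size=S) < rate_asa[sess_group]
    asa_day = test_day + rng.integers(1, SESSION_SPACING_DAYS + 1, size=S)
    asa2_hit = rng.uniform(size=S) < (0.1 if config.allow_multiple_attempts
                                      else 0.0)
    asa2_day = test_day + rng.integers(1, SESSION_SPACING_DAYS + 1, size=S)
    other_hit = rng.uniform(size=S) < rate_other[sess_group]
    other_day = test_day + rng.integers(1, SESSION_SPACING_DAYS + 1, size=S)
    other_type = np.array(OTHER_EVENT_TYPES)[
        rng.integers(len(OTHER_EVENT_TYPES), size=S)]

    event_rows = []
    for i in np.flatnonzero(withdrew):
        event_rows.append((pids[i], int(withdraw_day[i]), "withdrawal"))
    end_s = obs_end[sess_pid]
    for j in np.flatnonzero(asa_hit & (asa_day <= end_s)):
        event_rows.append((pids[sess_pid[j]], int(asa_day[j]), "asa"))
    for j in np.flatnonzero(asa_hit & asa2_hit & (asa2_day <= end_s)):
        event_rows.append((pids[sess_pid[j]], int(asa2_day[j]), "asa"))
    for j in np.flatnonzero(other_hit & (other_day <= end_s)):
        event_rows.append((pids[sess_pid[j]], int(other_day[j]),
                           str(other_type[j])))
    events_df = pd.DataFrame(event_rows, columns=[
        "participant_id", "event_day", "event_type"])
    events_df = events_df.sort_values(
        ["participant_id", "event_day"], kind="stable").reset_index(drop=True)
    return trials_df, sessions_df, events_df


def generate_stroop(seed: int, base_rt: float = 0.6,
                    interference: float = 0.12,
                    noise_sd: float = 0.1) -> pd.DataFrame:
    """A Stroop session: 52 congruent and 58 incongruent trials.

    Incongruent mean RT is ``base_rt * (1 + interference)`` before noise;
    RTs are truncated to stay positive.
    """
    if base_rt <= 0:
        raise ValueError("base_rt must be > 0")
    if interference < 0:
        raise ValueError("interference must be >= 0")
    rng = np.random.default_rng(seed)
    n_cong, n_incong = 52, 58
    cong = np.full(n_cong + n_incong, False)
    cong[:n_cong] = True
    rng.shuffle(cong)
    mean = np.where(cong, base_rt, base_rt * (1.0 + interference))
    rt = np.maximum(mean + rng.normal(0, noise_sd, cong.size)
                    if noise_sd > 0 else mean, 1e-3)
    return pd.DataFrame({"trial_index": np.arange(cong.size),
                         "congruent": cong, "rt": rt})


def generate_noncompliant_session(mode: str, seed: int) -> pd.DataFrame:
    """A session engineered to trip exactly one cleansing rule.

    * ``no_go_responses``: zero responses on all 225 trials;
    * ``single_foil_errors``: >= 90% false alarms on location foils only;
    * ``few_false_alarms``: exactly one false alarm (LBA-ineligible).
    """
    rng = np.random.default_rng(seed)
    df = generate_schedule(seed).trials.copy()
    n = len(df)
    df["responded"] = False
    df["rt"] = np.nan
    if mode == "no_go_responses":
        return df
    is_target = df["stim_class"] == "target"
    hit_rt = lambda k: np.round(rng.uniform(0.35, 0.75, k), 3)
    df.loc[is_target, "responded"] = True
    df.loc[is_target, "rt"] = hit_rt(int(is_target.sum()))
    if mode == "single_foil_errors":
        loc = df.index[df["stim_class"] == "location_foil"]
        hit = rng.choice(loc, size=int(np.ceil(0.95 * len(loc))), replace=False)
        df.loc[hit, "responded"] = True
        df.loc[hit, "rt"] = hit_rt(len(hit))
        ident = df.index[df["stim_class"] == "identity_foil"]
        one = rng.choice(ident, size=1)  # <10% on the other subtype
        df.loc[one, "responded"] = True
        df.loc[one, "rt"] = hit_rt(1)
        return df
    if mode == "few_false_alarms":
        foil = df.index[df["stim_class"] != "target"]
        one = rng.choice(foil, size=1)
        df.loc[one, "responded"] = True
        df.loc[one, "rt"] = hit_rt(1)
        return df
    raise ValueError(f"unknown noncompliance mode {mode!r}")
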