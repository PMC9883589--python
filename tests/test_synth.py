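"""Synthetic task, agent, cohort and Stroop generators."""

import numpy as np
import pandas as pd
import pytest

from gonogo.behavior import compliance_flags, filter_rts
from gonogo.lba import LBAParams, lba_eligible, prob_go_by_deadline
from gonogo.outcomes import label_all
from gonogo.synth import (CohortConfig, TRIAL_LENGTH, generate_cohort,
                          generate_noncompliant_session, generate_schedule,
                          generate_stroop, simulate_session,
                          simulate_trials_vectorized)


@pytest.mark.parametrize("seed", [0, 1, 2, 17, 12345])
def test_schedule_composition_exact_for_every_seed(seed):
    df = generate_schedule(seed).trials
    assert len(df) == 225
    assert (df["stim_class"] == "target").sum() == 144
    assert (df["stim_class"] == "identity_foil").sum() == 36
    loc = df[df["stim_class"] == "location_foil"]
    assert len(loc) == 45
    assert (loc["letter"] == "X").sum() == 36
    assert (loc["letter"] == "Y").sum() == 9
    # class labels consistent with letter/row geometry
    assert ((df["stim_class"] == "target")
            == ((df["letter"] == "X") & (df["row"] == "upper"))).all()
    assert df["position"].isin([1, 2, 3]).all()


def test_schedule_timing_and_seeded_determinism():
    a, b, c = generate_schedule(1), generate_schedule(1), generate_schedule(2)
    assert a.stimulus_duration + a.blank_duration == pytest.approx(1.5)
    pd.testing.assert_frame_equal(a.trials, b.trials)
    assert not a.trials.equals(c.trials)


def test_extreme_drifts_give_near_perfect_agent(schedule):
    params = LBAParams(t0=0.25, A=0.3, B_go=0.5, B_nogo=0.5,
                       v_target_go=6.0, v_target_nogo=-3.0,
                       v_foil_go=-3.0, v_foil_nogo=6.0)
    frames = [simulate_session(schedule, params, rng_seed=k)
              for k in range(45)]  # ~10k trials
    tr = pd.concat(frames, ignore_index=True)
    targets = tr[tr["stim_class"] == "target"]
    foils = tr[tr["stim_class"] != "target"]
    assert targets["responded"].mean() > 0.95
    assert foils["responded"].mean() < 0.10


def test_deterministic_race_reaction_time(schedule):
    # A=0, s->0: decision time is exactly b/v; RT = t0 + b/v = 0.7 s
    params = LBAParams(t0=0.2, A=0.0, B_go=1.0, B_nogo=1.0,
                       v_target_go=2.0, v_target_nogo=-5.0,
                       v_foil_go=-5.0, v_foil_nogo=2.0, s=1e-9)
    tr = simulate_session(schedule, params, rng_seed=0)
    target_rts = tr.loc[tr["stim_class"] == "target", "rt"]
    assert np.allclose(target_rts, 0.7, atol=1e-6)


def test_simulated_foil_go_rate_matches_closed_form(base_params):
    n = 100_000
    rng = np.random.default_rng(0)
    stim = np.full(n, "foil")
    responded, _ = simulate_trials_vectorized(
        stim, base_params.t0, base_params.A, base_params.b_go,
        base_params.b_nogo, base_params.v_target_go, base_params.v_target_nogo,
        base_params.v_foil_go, base_params.v_foil_nogo, base_params.s,
        TRIAL_LENGTH, rng)
    p_exact = prob_go_by_deadline("foil", base_params, TRIAL_LENGTH)
    se = np.sqrt(p_exact * (1 - p_exact) / n)
    assert abs(responded.mean() - p_exact) < 3 * se


def test_cohort_is_bit_reproducible_and_bounded_sessions():
    cfg = CohortConfig(n_participants=15, sessions_per_participant=3, seed=9)
    t1, s1, e1 = generate_cohort(cfg)
    t2, s2, e2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(s1, s2)
    pd.testing.assert_frame_equal(e1, e2)
    assert s1.groupby("participant_id").size().max() <= 3
    assert set(s1["session_label"]) == {"T1", "T2", "T3"}


def test_forced_event_rate_labels_every_asa_like_session_asa():
    cfg = CohortConfig(
        n_participants=20, seed=4, withdrawal_prob=0.0,
        group_proportions={"ASA-like": 1.0},
        event_rates={"ASA-like": {"asa": 1.0, "other": 0.0}})
    _, sessions, events = generate_cohort(cfg)
    labels = label_all(sessions, events)
    assert (labels["category"] == "ASA").all()


def test_planted_group_effects_visible_in_raw_behavior():
    cfg = CohortConfig(n_participants=300, seed=21)
    trials, sessions, _ = generate_cohort(cfg)
    filtered, _, _ = filter_rts(trials)
    from gonogo.behavior import score_all
    beh = score_all(filtered).merge(
        sessions[["participant_id", "session_label", "latent_group"]],
        on=["participant_id", "session_label"])
    mean = beh.groupby("latent_group")[["pct_misses", "pct_false_alarms"]].mean()
    assert mean.loc["ASA-like", "pct_misses"] > mean.loc["noSE-like", "pct_misses"]
    assert (mean.loc["OtherSE-like", "pct_false_alarms"]
            > mean.loc["noSE-like", "pct_false_alarms"])


def test_cohort_rejects_bad_configs():
    with pytest.raises(ValueError):
        CohortConfig(sessions_per_participant=4)
    with pytest.raises(ValueError):
        CohortConfig(group_proportions={"ASA-like": 0.5, "noSE-like": 0.2,
                                        "OtherSE-like": 0.2})
    with pytest.raises(ValueError):
        CohortConfig(group_param_means={"noSE-like": "not params"},
                     group_proportions={"noSE-like": 1.0})


@pytest.mark.parametrize("seed", [0, 7])
def test_stroop_counts_and_forced_interference(seed):
    from gonogo.behavior import stroop_dscore
    df = generate_stroop(seed)
    assert int(df["congruent"].sum()) == 52
    assert int((~df["congruent"]).sum()) == 58
    flat = generate_stroop(seed, interference=0.0, noise_sd=0.0)
    assert stroop_dscore(flat).d_score == pytest.approx(0.0)
    shifted = generate_stroop(seed, interference=0.2, noise_sd=0.0)
    assert stroop_dscore(shifted).d_score == pytest.approx(0.2)


def test_noncompliant_modes_trip_exactly_their_rule():
    silent = generate_noncompliant_session("no_go_responses", 0)
    assert compliance_flags(silent) == {"no_go_responses"}

    onesided = generate_noncompliant_session("single_foil_errors", 0)
    loc = onesided[onesided["stim_class"] == "location_foil"]
    ident = onesided[onesided["stim_class"] == "identity_foil"]
    assert loc["responded"].mean() >= 0.9
    assert ident["responded"].mean() < 0.1
    assert compliance_flags(onesided) == {"single_foil_errors"}

    sparse = generate_noncompliant_session("few_false_alarms", 0)
    n_fa = (sparse["responded"] & (sparse["stim_class"] != "target")).sum()
    assert n_fa == 1
    assert compliance_flags(sparse) == set()
    assert not lba_eligible(sparse)

    with pytest.raises(ValueError, match="unknown"):
        generate_noncompliant_session("bogus", 0)
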