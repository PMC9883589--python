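"""End-to-end pipeline: simulate -> score -> clean -> fit-LBA -> label -> model.

Every stage writes its table as CSV into the run directory; the run
manifest records the seed, row counts, sessions dropped per cleansing rule,
outcome category counts, and the model summaries. Two runs from the same
config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
import numpy as np
import pandas as pd

from . import __version__
from .behavior import compliance_flags, filter_rts, score_all
from .config import PipelineConfig, save_config
from .io import write_events, write_sessions, write_trials
from .lba import fit_lba, lba_eligible
from .outcomes import label_all
from .riskmodel import ModelSpec, fit_multinomial_robust
from .synth import generate_cohort

__all__ = ["run_pipeline"]

log = logging.getLogger("gonogo.pipeline")


def _stage(name, **counts):
    log.info("stage=%s %s", name,
             " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages, write tables + manifest under ``outdir``, return the
    manifest dict."""
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "gonogo_version": __version__,
                      "horizon_days": config.outcome.horizon}
    save_config(config, os.path.join(outdir, "config.yaml"))

    # --- simulate -----------------------------------------------------
    trials, sessions, events = generate_cohort(config.cohort)
    write_trials(trials, os.path.join(outdir, "trials.csv"))
    write_sessions(sessions, os.path.join(outdir, "sessions.csv"))
    write_events(events, os.path.join(outdir, "events.csv"))
    _stage("simulate", trials=len(trials), sessions=len(sessions),
           events=len(events))

    # --- score + clean ------------------------------------------------
    filtered, n_short, n_long = filter_rts(
        trials, config.rt_filter.low, config.rt_filter.high)
    dropped = {"no_go_responses": 0, "single_foil_errors": 0}
    keep_keys = []
    for key, sess in filtered.groupby(["participant_id", "session_label"]):
        flags = compliance_flags(sess)
        if flags:
            for f in flags:
                dropped[f] += 1
        else:
            keep_keys.append(key)
    keep_idx = pd.MultiIndex.from_tuples(keep_keys)
    mask = filtered.set_index(
        ["participant_id", "session_label"]).index.isin(keep_idx)
    clean = filtered[mask]
    behavior = score_all(clean)
    behavior.to_csv(os.path.join(outdir, "behavior.csv"), index=False)
    _stage("score", sessions_scored=len(behavior),
           responses_dropped_short=n_short, responses_dropped_long=n_long,
           **{f"dropped_{k}": v for k, v in dropped.items()})

    # --- fit-lba ------------------------------------------------------
    lba_rows = []
    n_ineligible = 0
    if config.lba.enabled:
        mcmc = {"n_chains": config.lba.n_chains,
                "n_steps": config.lba.n_steps,
                "burn_in": config.lba.burn_in}
        rng = np.random.default_rng(config.seed + 1)
        for (pid, label), sess in clean.groupby(
                ["participant_id", "session_label"]):
            if not lba_eligible(sess):
                n_ineligible += 1
                continue
            summary = fit_lba(
                sess, mcmc={**mcmc, "seed": int(rng.integers(2**31))},
                deadline=config.lba.deadline)
            row = {"participant_id": pid, "session_label": label,
                   **summary.medians,
                   "converged": summary.converged}
            if summary.derived is not None:
                row.update(response_bias_go=summary.derived.response_bias_go,
                           de_targets=summary.derived.de_targets,
                           de_foils=summary.derived.de_foils)
            lba_rows.append(row)
        lba_table = pd.DataFrame(lba_rows)
        lba_table.to_csv(os.path.join(outdir, "lba.csv"), index=False)
        _stage("fit-lba", sessions_fit=len(lba_rows),
               lba_ineligible=n_ineligible)
    dropped["lba_ineligible"] = n_ineligible

    # --- label --------------------------------------------------------
    outcomes = label_all(sessions, events, config.outcome.horizon,
                         config.outcome.study_length)
    outcomes.to_csv(os.path.join(outdir, "outcomes.csv"), index=False)
    category_counts = outcomes["category"].value_counts().to_dict()
    dropped["censored"] = int(category_counts.get("censored", 0))
    _stage("label", **{f"n_{k}": v for k, v in category_counts.items()})

    # --- model --------------------------------------------------------
    merged = (behavior
              .merge(sessions, on=["participant_id", "session_label"])
              .merge(outcomes, on=["participant_id", "session_label"]))
    spec = ModelSpec(predictors=config.model.behavioral_predictors,
                     covariates=config.model.covariates)
    fit = fit_multinomial_robust(merged, spec)
    reports = {"behavioral": _fit_report(fit)}

    if config.lba.enabled and lba_rows:
        lba_ok = pd.DataFrame(lba_rows)
        lba_ok = lba_ok[lba_ok["converged"]]
        merged_lba = merged.merge(
            lba_ok, on=["participant_id", "session_label"])
        if merged_lba["category"].nunique() >= 2:
            spec_lba = ModelSpec(predictors=config.model.lba_predictors,
                                 covariates=config.model.covariates)
            reports["lba"] = _fit_report(
                fit_multinomial_robust(merged_lba, spec_lba))

    with open(os.path.join(outdir, "model_report.json"), "w") as fh:
        json.dump(reports, fh, indent=2)
    _stage("model", n_sessions=fit.n_sessions, n_clusters=fit.n_clusters)

    manifest.update(
        n_trials=len(trials),
        n_sessions=len(sessions),
        n_events=len(events),
        n_sessions_scored=len(behavior),
        responses_dropped_short=n_short,
        responses_dropped_long=n_long,
        dropped_sessions=dropped,
        outcome_counts=category_counts,
        model=reports,
    )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _fit_report(fit) -> dict:
    tab = fit.table.reset_index()
    return {
        "n_sessions": fit.n_sessions,
        "n_clusters": fit.n_clusters,
        "n_dropped_censored": fit.n_dropped_censored,
        "converged": fit.converged,
        "outcome_categories": list(fit.outcome_categories),
        "coefficients": [
            {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
             for k, v in rec.items()}
            for rec in tab.to_dict(orient="records")
        ],
    }
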