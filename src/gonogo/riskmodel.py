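"""Multinomial risk models with within-participant clustering.

Outcome category (ASA, OtherSE; noSE as the reference) is regressed on
per-session predictors — Go/No-go behavioral scores or LBA-derived
metrics — plus covariates, using a baseline-category multinomial logit.
Repeated sessions from the same participant are handled GEE-style: the
estimating equations under an independence working correlation are exactly
the multinomial-logit score equations, so the model is fit by maximum
likelihood and the covariance is replaced by a cluster-robust sandwich over
participants. Results are odds ratios with 95% Wald confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "RiskFitResult",
    "fit_multinomial_robust",
    "or_for_delta",
    "model_table",
    "DEFAULT_COVARIATES",
]

OUTCOME_ORDER = ("noSE", "ASA", "OtherSE")  # first category is the reference

DEFAULT_COVARIATES = ("session_label", "lifetime_asa_count", "ssi", "age",
                      "gender", "tbi", "treatment_arm", "stroop_d")


@dataclass(frozen=True)
class ModelSpec:
    """Which columns enter the model and how rows are clustered."""

    predictors: tuple[str, ...]
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    cluster_variable: str = "participant_id"
    reference_category: str = "noSE"
    outcome_variable: str = "category"

    def __post_init__(self):
        if self.reference_category != "noSE":
            raise ValueError("the reference category is fixed to noSE")


@dataclass(frozen=True)
class RiskFitResult:
    """Coefficients, cluster-robust inference, and odds ratios.

    ``table`` has a row per (outcome, term) with columns beta, se, OR,
    ci_low, ci_high, p. The reference category contributes no rows.
    """

    table: pd.DataFrame
    cov: pd.DataFrame
    n_sessions: int
    n_clusters: int
    n_dropped_censored: int
    converged: bool
    outcome_categories: tuple[str, ...]

    def odds_ratio(self, outcome: str, term: str) -> float:
        return float(self.table.loc[(outcome, term), "OR"])

    def beta(self, outcome: str, term: str) -> float:
        return float(self.table.loc[(outcome, term), "beta"])

    def p_value(self, outcome: str, term: str) -> float:
        return float(self.table.loc[(outcome, term), "p"])


def _design_matrix(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    cols = {}
    for term in terms:
        if term == "session_label":
            # categorical testing session, T1 as reference
            labels = pd.Categorical(data[term], categories=["T1", "T2", "T3"])
            for lab in ("T2", "T3"):
                if (labels == lab).any():
                    cols[f"session_{lab}"] = (labels == lab).astype(float)
        else:
            cols[term] = data[term].astype(float).to_numpy()
    X = pd.DataFrame(cols, index=data.index)
    X.insert(0, "const", 1.0)
    return X


def fit_multinomial_robust(data: pd.DataFrame, spec: ModelSpec,
                           maxiter: int = 200) -> RiskFitResult:
    """Fit the baseline-category multinomial model with a cluster-robust
    sandwich covariance over participants.

    Censored sessions are dropped before fitting. Raises on single-category
    data or missing values in modeled columns; flags (rather than hides)
    non-convergence or separation.
    """
    df = data[data[spec.outcome_variable] != "censored"].copy()
    n_dropped = len(data) - len(df)
    modeled = [spec.outcome_variable, spec.cluster_variable,
               *spec.predictors, *spec.covariates]
    missing_cols = [c for c in modeled if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing model columns: {missing_cols}")
    if df[modeled].isna().any().any():
        bad = df[modeled].isna().any()
        raise ValueError(f"missing values in modeled columns: "
                         f"{list(bad[bad].index)}")

    present = [c for c in OUTCOME_ORDER if (df[spec.outcome_variable] == c).any()]
    if len(present) < 2:
        raise ValueError("need at least two outcome categories to fit")
    if "noSE" not in present:
        raise ValueError("reference category noSE absent from data")
    y = pd.Categorical(df[spec.outcome_variable], categories=present).codes
    X = _design_matrix(df, tuple(spec.predictors) + tuple(spec.covariates))
    groups = pd.Categorical(df[spec.cluster_variable]).codes

    model = sm.MNLogit(y, X.to_numpy())
    with np.errstate(over="ignore", invalid="ignore"):
        res = model.fit(disp=0, maxiter=maxiter, cov_type="cluster",
                        cov_kwds={"groups": groups})
    params = np.asarray(res.params)            # (n_terms, n_cat-1)
    bse = np.asarray(res.bse)
    converged = bool(res.mle_retvals.get("converged", False))
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        converged = False                      # optimizer blow-up
    elif np.max(np.abs(params)) > 15:
        converged = False                      # quasi-separation

    terms = list(X.columns)
    outcomes = present[1:]                     # non-reference, in fit order
    z = 1.959963984540054                      # Phi^{-1}(0.975)
    rows = []
    from scipy.stats import norm
    for j, outc in enumerate(outcomes):
        for i, term in enumerate(terms):
            b, se = params[i, j], bse[i, j]
            rows.append({
                "outcome": outc, "term": term, "beta": b, "se": se,
                "OR": np.exp(b),
                "ci_low": np.exp(b - z * se), "ci_high": np.exp(b + z * se),
                "p": 2 * norm.sf(abs(b) / se) if se > 0 else np.nan,
            })
    table = pd.DataFrame(rows).set_index(["outcome", "term"])
    cov = pd.DataFrame(np.asarray(res.cov_params()))
    return RiskFitResult(
        table=table, cov=cov,
        n_sessions=len(df),
        n_clusters=int(pd.Series(groups).nunique()),
        n_dropped_censored=n_dropped,
        converged=converged,
        outcome_categories=tuple(present),
    )


def or_for_delta(beta: float, delta: float) -> float:
    """Odds ratio for a ``delta``-unit change: ``exp(beta * delta)``.

    Used to translate a per-unit coefficient into the odds change implied
    by an observed group mean difference.
    """
    if not (np.isfinite(beta) and np.isfinite(delta)):
        raise ValueError("beta and delta must be finite")
    return float(np.exp(beta * delta))


def model_table(fit: RiskFitResult, alpha: float = 0.05) -> pd.DataFrame:
    """Render a report: one row per term, OR (95% CI) and p per outcome.

    Flags terms with p below ``alpha``.
    """
    if not fit.converged:
        raise ValueError("refusing to render a non-converged fit")
    out = {}
    for outcome in fit.table.index.get_level_values("outcome").unique():
        sub = fit.table.loc[outcome]
        out[(outcome, "OR (95% CI)")] = [
            f"{r.OR:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
            for r in sub.itertuples()
        ]
        out[(outcome, "p")] = [round(float(r.p), 4) for r in sub.itertuples()]
        out[(outcome, "significant")] = [bool(r.p < alpha) for r in sub.itertuples()]
        index = sub.index
    report = pd.DataFrame(out, index=index)
    report.index.name = "term"
    return report
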