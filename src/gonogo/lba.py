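"""Linear ballistic accumulator (LBA) adapted to the Go/No-go task.

The LBA (Brown & Heathcote, 2008) models a speeded choice as a race between
independent linear evidence accumulators. Each accumulator starts at a point
drawn uniformly from ``[0, A]`` and rises with a slope drawn from a normal
distribution with mean ``v`` (the *drift rate*) and standard deviation ``s``;
the first accumulator to reach its threshold ``b = A + B`` triggers its
response, at time ``t0 + (b - start) / slope``.

In the Go/No-go adaptation there are two accumulators (Go, No-go) but only
Go terminations are observable as key presses: a "no response" trial is
*censored*, absorbing both No-go wins and races in which neither accumulator
crossed threshold before the response deadline. The likelihood therefore
combines the defective density of Go wins at the observed RT with the
censored probability of no Go response by the deadline.

Eight parameters are free per session: ``t0``, ``A``, the two boundary
offsets ``B_go``/``B_nogo``, and four mean drifts (one per stimulus-class x
accumulator pair). The drift SD ``s`` is fixed at 1.0 as the standard
identifiability constraint.

Derived session-level metrics:

* response bias for Go: ``100 * (B_nogo - B_go)`` — positive values mean
  the Go threshold is closer, so Go responses trigger more easily;
* decisional efficiency for targets: ``v_target_go - v_target_nogo``;
* decisional efficiency for foils: ``v_foil_nogo - v_foil_go`` — the drift
  advantage of the correct over the incorrect accumulator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import integrate
from scipy.special import ndtr

__all__ = [
    "LBAParams",
    "DerivedMetrics",
    "PriorSpec",
    "PosteriorSummary",
    "IneligibleSessionError",
    "single_cdf",
    "single_pdf",
    "defective_go_density",
    "prob_go_by_deadline",
    "trial_loglik",
    "session_loglik",
    "derived_metrics",
    "lba_eligible",
    "fit_lba",
    "default_priors",
    "diffuse_priors",
    "FREE_PARAM_NAMES",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_A_EPS = 1e-9          # below this the U[0,A] start point is treated as degenerate
_DENSITY_FLOOR = 1e-300
_QUAD_NODES = 64       # Gauss-Legendre rule used inside the MCMC likelihood

#: the eight free parameters, in packing order used by the sampler
FREE_PARAM_NAMES = (
    "t0", "A", "B_go", "B_nogo",
    "v_target_go", "v_target_nogo", "v_foil_go", "v_foil_nogo",
)


def _npdf(z):
    return np.exp(-0.5 * np.square(z)) / _SQRT_2PI


@dataclass(frozen=True)
class LBAParams:
    """The eight free LBA parameters plus the fixed drift SD ``s``.

    Thresholds are ``b = A + B`` per accumulator; ``B > 0`` keeps the
    threshold strictly above the start-point range.
    """

    t0: float
    A: float
    B_go: float
    B_nogo: float
    v_target_go: float
    v_target_nogo: float
    v_foil_go: float
    v_foil_nogo: float
    s: float = 1.0

    def __post_init__(self):
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if self.A < 0:
            raise ValueError(f"A must be >= 0, got {self.A}")
        if self.B_go <= 0 or self.B_nogo <= 0:
            raise ValueError("boundary offsets B must be > 0")
        if self.s <= 0:
            raise ValueError("drift SD s must be > 0")

    @property
    def b_go(self) -> float:
        return self.A + self.B_go

    @property
    def b_nogo(self) -> float:
        return self.A + self.B_nogo

    def drifts(self, stim_class: str) -> tuple[float, float]:
        """Mean drifts ``(go, nogo)`` for a stimulus class.

        Identity and location foils share the foil drifts: the model has one
        foil class.
        """
        if stim_class == "target":
            return self.v_target_go, self.v_target_nogo
        if stim_class in ("foil", "identity_foil", "location_foil"):
            return self.v_foil_go, self.v_foil_nogo
        raise ValueError(f"unknown stimulus class {stim_class!r}")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FREE_PARAM_NAMES])

    @classmethod
    def from_free_values(cls, theta, s: float = 1.0) -> "LBAParams":
        return cls(**dict(zip(FREE_PARAM_NAMES, map(float, theta))), s=s)


@dataclass(frozen=True)
class DerivedMetrics:
    """Session-level cognitive metrics derived from the LBA parameters."""

    response_bias_go: float   # 100 * (B_nogo - B_go)
    de_targets: float         # v_target_go - v_target_nogo
    de_foils: float           # v_foil_nogo - v_foil_go


def derived_metrics(params: LBAParams) -> DerivedMetrics:
    """Response bias for Go and decisional efficiencies for targets/foils."""
    return DerivedMetrics(
        response_bias_go=100.0 * (params.B_nogo - params.B_go),
        de_targets=params.v_target_go - params.v_target_nogo,
        de_foils=params.v_foil_nogo - params.v_foil_go,
    )


# ---------------------------------------------------------------------------
# closed-form single-accumulator race quantities
# ---------------------------------------------------------------------------

def single_cdf(t, A, b, v, s):
    """P(an accumulator with U[0,A] start and N(v, s) slope crossed b by t).

    ``t`` is decision time (non-decision time already removed) and may be an
    array. Negative slopes never cross, so the limit as t -> inf is below 1
    when P(slope <= 0) > 0. As ``A -> 0`` the expression reduces to
    ``Phi((t*v - b)/(t*s))``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("decision time t must be > 0")
    if not (b > A >= 0):
        raise ValueError("need b > A >= 0")
    if s <= 0:
        raise ValueError("drift SD s must be > 0")
    ts = t * s
    if A < _A_EPS:
        out = ndtr((t * v - b) / ts)
    else:
        z1 = (b - A - t * v) / ts
        z2 = (b - t * v) / ts
        out = (
            1.0
            + (b - A - t * v) / A * ndtr(z1)
            - (b - t * v) / A * ndtr(z2)
            + ts / A * (_npdf(z1) - _npdf(z2))
        )
    return np.clip(out, 0.0, 1.0)


def single_pdf(t, A, b, v, s):
    """Density (per second) of first threshold crossing at decision time t."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("decision time t must be > 0")
    if not (b > A >= 0):
        raise ValueError("need b > A >= 0")
    if s <= 0:
        raise ValueError("drift SD s must be > 0")
    ts = t * s
    if A < _A_EPS:
        out = b / (np.square(t) * s) * _npdf((t * v - b) / ts)
    else:
        z1 = (b - A - t * v) / ts
        z2 = (b - t * v) / ts
        out = (-v * ndtr(z1) + s * _npdf(z1) + v * ndtr(z2) - s * _npdf(z2)) / A
    return np.maximum(out, 0.0)


def defective_go_density(t, stim_class: str, params: LBAParams):
    """Density of a Go response at time ``t`` after stimulus onset.

    The Go accumulator crosses at decision time ``t - t0`` while the No-go
    accumulator has not yet crossed. Zero for ``t <= t0`` (not an error:
    the race cannot have finished).
    """
    t = np.asarray(t, dtype=float)
    v_go, v_nogo = params.drifts(stim_class)
    dt = t - params.t0
    out = np.zeros_like(dt, dtype=float)
    ok = dt > 0
    if np.any(ok):
        d = dt[ok] if dt.ndim else dt
        dens = single_pdf(d, params.A, params.b_go, v_go, params.s) * (
            1.0 - single_cdf(d, params.A, params.b_nogo, v_nogo, params.s)
        )
        if dt.ndim:
            out[ok] = dens
        else:
            out = np.asarray(dens)
    return out if dt.ndim else float(out)


def prob_go_by_deadline(stim_class: str, params: LBAParams,
                        deadline: float) -> float:
    """P(a Go response is emitted by ``deadline``), by adaptive quadrature.

    Returns 0 when the deadline precedes the non-decision time. The
    complement is the censored "no response" mass: No-go wins plus races in
    which neither accumulator finished in time.
    """
    if deadline <= 0:
        raise ValueError("deadline must be > 0")
    if deadline <= params.t0:
        return 0.0
    val, _ = integrate.quad(
        lambda u: defective_go_density(u, stim_class, params),
        params.t0, deadline, epsabs=1e-8, limit=200,
    )
    return float(min(max(val, 0.0), 1.0))


# ---------------------------------------------------------------------------
# censored session likelihood
# ---------------------------------------------------------------------------

def _session_arrays(trials: pd.DataFrame):
    """Split a scored session into the sufficient pieces for the likelihood.

    Trials whose response was removed by the RT filter are non-responses
    here: with the censoring deadline equal to the filter's upper cut, the
    censored mass ``1 - P(Go by deadline)`` absorbs exactly the slow
    responses the filter discarded (plus No-go wins and non-termination),
    so the likelihood stays correctly specified under the filtering.
    """
    df = trials
    is_target = (df["stim_class"] == "target").to_numpy()
    responded = df["responded"].astype(bool).to_numpy()
    rt = df["rt"].to_numpy(dtype=float)
    # sorted so the likelihood (and hence the fit) is exactly invariant to
    # trial order
    return (
        np.sort(rt[responded & is_target]),
        np.sort(rt[responded & ~is_target]),
        int(np.sum(~responded & is_target)),
        int(np.sum(~responded & ~is_target)),
    )


def session_loglik(trials: pd.DataFrame, params: LBAParams,
                   deadline: float = 1.0) -> float:
    """Censored log-likelihood of one RT-filtered session.

    Responded trials contribute the log defective Go density at their RT;
    non-responded trials contribute ``log(1 - P(Go by deadline))`` for their
    stimulus class. An observed RT outside ``(t0, deadline]`` is impossible
    under the model and yields ``-inf``.
    """
    rt_t, rt_f, n_cens_t, n_cens_f = _session_arrays(trials)
    theta = params.free_values()[None, :]
    data = (rt_t, rt_f, n_cens_t, n_cens_f)
    return float(_batch_loglik(theta, data, deadline, params.s)[0])


def trial_loglik(trial, params: LBAParams, deadline: float = 1.0) -> float:
    """Log-likelihood contribution of a single trial (see session_loglik)."""
    if isinstance(trial, pd.Series):
        trial = trial.to_frame().T
    responded = bool(trial["responded"].iloc[0])
    rt = float(trial["rt"].iloc[0]) if responded else np.nan
    if responded and not (params.t0 < rt <= deadline):
        warnings.warn(
            f"observed RT {rt:.3f}s outside the admissible interval "
            f"({params.t0:.3f}, {deadline:.3f}]; log-likelihood is -inf",
            stacklevel=2,
        )
        return -np.inf
    return session_loglik(trial, params, deadline)


def _batch_loglik(theta: np.ndarray, data, deadline: float,
                  s: float = 1.0) -> np.ndarray:
    """Vectorized censored log-likelihood over a batch of parameter vectors.

    ``theta`` has shape (K, 8) in FREE_PARAM_NAMES order; ``data`` is the
    tuple produced by :func:`_session_arrays`. Broadcasting over K keeps the
    per-step cost of the ensemble sampler low.
    """
    rt_t, rt_f, n_cens_t, n_cens_f = data
    t0, A, B_go, B_nogo, vtg, vtn, vfg, vfn = (theta[:, i] for i in range(8))
    A = np.maximum(A, _A_EPS)
    b_go = (A + B_go)[:, None]
    b_nogo = (A + B_nogo)[:, None]
    A2 = A[:, None]
    K = theta.shape[0]
    ll = np.zeros(K)

    def _cdf(dt, b, v):
        ts = dt * s
        z1 = (b - A2 - dt * v) / ts
        z2 = (b - dt * v) / ts
        out = (1.0 + (b - A2 - dt * v) / A2 * ndtr(z1)
               - (b - dt * v) / A2 * ndtr(z2)
               + ts / A2 * (_npdf(z1) - _npdf(z2)))
        return np.clip(out, 0.0, 1.0)

    def _pdf(dt, b, v):
        ts = dt * s
        z1 = (b - A2 - dt * v) / ts
        z2 = (b - dt * v) / ts
        out = (-v * ndtr(z1) + s * _npdf(z1) + v * ndtr(z2) - s * _npdf(z2)) / A2
        return np.maximum(out, 0.0)

    # responded trials: defective Go density at the observed RTs
    for rt, v_go, v_nogo in ((rt_t, vtg, vtn), (rt_f, vfg, vfn)):
        if rt.size == 0:
            continue
        dt = rt[None, :] - t0[:, None]           # (K, n)
        bad = dt <= 0
        dt = np.where(bad, 1.0, dt)
        dens = _pdf(dt, b_go, v_go[:, None]) * (1.0 - _cdf(dt, b_nogo, v_nogo[:, None]))
        dens = np.where(bad, 0.0, dens)
        ll += np.log(np.maximum(dens, _DENSITY_FLOOR)).sum(axis=1)

    # censored trials: log(1 - P(Go by deadline)), computed directly as the
    # no-response mass P(No-go wins by T) + P(neither crossed by T) — the
    # second term is closed form, and summing the small pieces keeps the log
    # accurate when the censored mass is tiny. The win integral runs in log
    # decision time: crossing densities spike just above zero at large
    # drift, and log-spaced nodes concentrate there.
    if n_cens_t or n_cens_f:
        nodes, weights = _leggauss_cached(_QUAD_NODES)
        dt_max = (deadline - t0)[:, None]        # (K, 1)
        y_lo, y_hi = np.log(1e-5), np.log(dt_max)
        half = 0.5 * (y_hi - y_lo)               # (K, 1)
        u = np.exp(y_lo + half * (nodes[None, :] + 1.0))
        for n_cens, v_go, v_nogo in ((n_cens_t, vtg, vtn), (n_cens_f, vfg, vfn)):
            if n_cens == 0:
                continue
            vg, vn = v_go[:, None], v_nogo[:, None]
            dens = _pdf(u, b_nogo, vn) * (1.0 - _cdf(u, b_go, vg))
            p_nogo_win = np.clip(((dens * u) * weights[None, :]).sum(axis=1)
                                 * half[:, 0], 0.0, 1.0)
            p_neither = ((1.0 - _cdf(dt_max, b_go, vg))
                         * (1.0 - _cdf(dt_max, b_nogo, vn)))[:, 0]
            p_none = np.clip(p_nogo_win + p_neither, 0.0, 1.0)
            ll += n_cens * np.log(np.maximum(p_none, _DENSITY_FLOOR))
    return ll


_LEGGAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _leggauss_cached(n: int):
    if n not in _LEGGAUSS_CACHE:
        _LEGGAUSS_CACHE[n] = leggauss(n)
    return _LEGGAUSS_CACHE[n]


# ---------------------------------------------------------------------------
# eligibility, priors, fitting
# ---------------------------------------------------------------------------

class IneligibleSessionError(ValueError):
    """Raised when a session cannot support LBA fitting."""


def lba_eligible(trials_or_summary) -> bool:
    """True iff the session has at least 2 retained false alarms.

    With fewer than two foil responses the RT variance on errors is
    undefined and the model is not identified for that session.
    """
    obj = trials_or_summary
    if hasattr(obj, "pct_false_alarms"):  # BehavioralSummary
        n_fa = obj.pct_false_alarms / 100.0 * obj.n_foils_scored
        return bool(round(n_fa) >= 2)
    df = obj
    if "rt_dropped" in df.columns:
        df = df[df["rt_dropped"].isna()]
    n_fa = int((df["responded"].astype(bool) & (df["stim_class"] != "target")).sum())
    return n_fa >= 2


@dataclass(frozen=True)
class PriorSpec:
    """Independent truncated-normal priors, one (loc, scale, low, high) per
    free parameter in FREE_PARAM_NAMES order."""

    loc: np.ndarray
    scale: np.ndarray
    low: np.ndarray
    high: np.ndarray

    def __post_init__(self):
        for arr in (self.loc, self.scale, self.low, self.high):
            if np.asarray(arr).shape != (len(FREE_PARAM_NAMES),):
                raise ValueError("prior arrays must have one entry per free parameter")
        if np.any(self.low >= self.high):
            raise ValueError("prior support bounds must satisfy low < high")

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalized log prior for a (K, 8) batch; -inf outside support."""
        inside = np.all((theta > self.low) & (theta < self.high), axis=1)
        lp = -0.5 * np.square((theta - self.loc) / self.scale).sum(axis=1)
        return np.where(inside, lp, -np.inf)

    def median(self) -> np.ndarray:
        return np.clip(self.loc, self.low + 1e-6, self.high - 1e-6)


def default_priors() -> PriorSpec:
    """Weakly-informative priors for the Go/No-go LBA.

    t0 on (0.05, 0.6) s centered at 0.3 covers plausible encoding+motor
    times; A and the boundary offsets live on (0, ~2.5) centered at 0.5.
    Drift priors are class-informed, the standard practice for race models
    of two-choice data: accumulators matching the correct response are
    centered at 2, mismatching accumulators at 0.5. This matters here
    because No-go wins are never observed directly: with fully exchangeable
    drift priors the posterior has a soft ridge trading the No-go boundary
    against the No-go drifts, and session point estimates wander along it.
    """
    return PriorSpec(
        loc=np.array([0.3, 0.5, 0.5, 0.5, 2.0, 0.5, 0.5, 2.0]),
        scale=np.array([0.1, 0.5, 0.35, 0.35, 1.5, 1.0, 1.0, 1.5]),
        low=np.array([0.05, 0.0, 0.01, 0.01, -4.0, -4.0, -4.0, -4.0]),
        high=np.array([0.6, 2.0, 2.5, 2.5, 7.0, 7.0, 7.0, 7.0]),
    )


def diffuse_priors() -> PriorSpec:
    """Near-flat priors (sensitivity analysis): exchangeable drifts centered
    at 1 with scale 2, A/B on (0, 4). Expect noisier point estimates."""
    return PriorSpec(
        loc=np.array([0.3, 0.5, 0.5, 0.5, 1.0, 1.0, 1.0, 1.0]),
        scale=np.array([0.1, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 2.0]),
        low=np.array([0.05, 0.0, 1e-3, 1e-3, -50.0, -50.0, -50.0, -50.0]),
        high=np.array([0.6, 4.0, 4.0, 4.0, 50.0, 50.0, 50.0, 50.0]),
    )


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior medians, derived metrics and convergence diagnostics.

    ``point_estimates`` is None when the sampler failed the scale-reduction
    contract (any R-hat > 1.1); diagnostics are always reported.
    """

    point_estimates: LBAParams | None
    derived: DerivedMetrics | None
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    n_samples: int
    medians: dict[str, float] = field(default_factory=dict)


_DEFAULT_MCMC = {"n_chains": 32, "n_steps": 3000, "burn_in": 1500, "seed": 0}


def fit_lba(trials: pd.DataFrame, prior: PriorSpec | None = None,
            mcmc: dict | None = None, deadline: float = 1.0,
            prior_only: bool = False) -> PosteriorSummary:
    """Bayesian fit of the eight free LBA parameters to one session.

    Uses an affine-invariant ensemble sampler (emcee) over the censored race
    likelihood; the drift SD ``s`` stays fixed at 1.0. Point estimates are
    the componentwise posterior medians. The fit is deterministic given
    ``mcmc['seed']``.

    Parameters
    ----------
    trials
        RT-filtered trial table for a single session.
    prior
        Truncated-normal prior specification; defaults to
        :func:`default_priors`.
    mcmc
        ``{"n_chains", "n_steps", "burn_in", "seed"}`` overrides. "Chains"
        are ensemble walkers; R-hat and ESS are computed across them.
    deadline
        Censoring deadline in seconds; must match the RT filter's upper cut.
    prior_only
        Skip the likelihood (prior-predictive check).
    """
    import emcee

    prior = prior or default_priors()
    settings = dict(_DEFAULT_MCMC)
    if mcmc:
        settings.update(mcmc)
    nwalk, nsteps = int(settings["n_chains"]), int(settings["n_steps"])
    burn = int(settings["burn_in"])
    if burn >= nsteps:
        raise ValueError("burn_in must be < n_steps")
    seed = int(settings["seed"])

    data = _session_arrays(trials)
    rt_t, rt_f, n_cens_t, n_cens_f = data
    n_scored = rt_t.size + rt_f.size + n_cens_t + n_cens_f
    if n_scored == 0:
        raise ValueError("no retained trials: cannot fit")
    if not prior_only and not lba_eligible(trials):
        raise IneligibleSessionError(
            "session has <2 retained false alarms; LBA not identified"
        )
    if rt_t.size + rt_f.size:
        all_rt = np.concatenate([rt_t, rt_f])
        if np.any(all_rt > deadline) or np.any(all_rt <= 0):
            raise ValueError("responded RTs must lie in (0, deadline]; filter first")

    ndim = len(FREE_PARAM_NAMES)

    def log_prob(theta2d):
        lp = prior.log_prior(theta2d)
        if not prior_only:
            ok = np.isfinite(lp)
            if np.any(ok):
                ll = np.full(theta2d.shape[0], -np.inf)
                ll[ok] = _batch_loglik(theta2d[ok], data, deadline)
                lp = np.where(ok, lp + ll, -np.inf)
        return lp

    rng = np.random.default_rng(seed)
    center = _map_start(log_prob, prior, data, rng)
    p0 = np.clip(
        center + 0.02 * np.maximum(np.abs(center), 0.05)
        * rng.standard_normal((nwalk, ndim)),
        prior.low + 1e-6, prior.high - 1e-6,
    )
    for w in range(nwalk):  # nudge any walker stuck at zero density
        for _ in range(100):
            if np.isfinite(log_prob(p0[w][None, :])[0]):
                break
            p0[w] = np.clip(center + 0.01 * rng.standard_normal(ndim),
                            prior.low + 1e-6, prior.high - 1e-6)
        else:  # pragma: no cover - pathological data
            raise RuntimeError("could not initialize walkers at finite density")

    # differential-evolution moves handle the correlated, ridge-shaped
    # posterior far better than the default stretch move here
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalk, ndim, log_prob, vectorize=True,
                                    moves=moves)
    sampler._random = np.random.RandomState(seed)
    sampler.run_mcmc(p0, nsteps, progress=False)

    chain = sampler.get_chain(discard=burn)          # (steps, walkers, ndim)
    rhat, ess = _convergence(chain)
    converged = all(r < 1.1 for r in rhat.values()) and all(
        e > 400 for e in ess.values()
    )
    flat = chain.reshape(-1, ndim)
    med = np.median(flat, axis=0)
    medians = dict(zip(FREE_PARAM_NAMES, map(float, med)))
    emit = all(r < 1.1 for r in rhat.values())
    point = LBAParams.from_free_values(med) if emit else None
    return PosteriorSummary(
        point_estimates=point,
        derived=derived_metrics(point) if point is not None else None,
        rhat=rhat,
        ess=ess,
        converged=converged,
        n_samples=flat.shape[0],
        medians=medians,
    )


def _map_start(log_prob, prior: PriorSpec, data, rng) -> np.ndarray:
    """Cheap multi-start Nelder-Mead search for a high-posterior point to
    seed the walkers; burn-in then only has to explore, not travel."""
    from scipy.optimize import minimize

    rt_t, rt_f, _, _ = data
    rts = np.concatenate([rt_t, rt_f])
    start0 = prior.median().copy()
    if rts.size:  # t0 must undercut the fastest retained response
        start0[0] = min(start0[0], 0.8 * float(rts.min()))
    best, best_val = start0, -log_prob(start0[None, :])[0]
    for k in range(3):
        x0 = start0 if k == 0 else np.clip(
            start0 + 0.2 * prior.scale * rng.standard_normal(start0.size),
            prior.low + 1e-4, prior.high - 1e-4)
        res = minimize(lambda x: -log_prob(x[None, :])[0], x0,
                       method="Nelder-Mead",
                       options={"maxfev": 1500, "xatol": 1e-4, "fatol": 1e-4})
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    return np.clip(best, prior.low + 1e-5, prior.high - 1e-5)


def _convergence(chain: np.ndarray) -> tuple[dict, dict]:
    """Split-R-hat and bulk ESS per parameter, walkers treated as chains."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        posterior = {
            name: np.swapaxes(chain[:, :, i], 0, 1)
            for i, name in enumerate(FREE_PARAM_NAMES)
        }
        idata = az.convert_to_dataset(posterior)
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in FREE_PARAM_NAMES}
    ess = {k: float(ess_ds[k].values) for k in FREE_PARAM_NAMES}
    return rhat, ess
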