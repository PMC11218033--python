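"""Four-parameter Wiener diffusion model of binary effort choices.

A single accumulator starts at ``a * w`` between an absorbing lower boundary
at 0 (low-effort / low-reward choice, "LR") and an upper boundary at ``a``
(high-effort / high-reward choice, "HR"), drifts at rate ``v`` (positive =
toward HR) with unit diffusion coefficient, and the response latency is the
first-passage time plus a non-decision offset ``t0``.  The diffusion
coefficient is fixed at 1 as the scaling convention; there are no
inter-trial variability parameters.

The module provides

* the closed-form boundary-choice probability,
* the defective first-passage-time density via the classical small-time /
  large-time series expansions with automatic regime switching,
* two simulators (Euler–Maruyama with a Brownian-bridge within-step
  crossing correction, and exact inverse-CDF sampling from the series
  density),
* per-participant maximum-likelihood fitting with multi-start,
* the participant inclusion filter used before diffusion modelling, and
* a parameter-recovery harness.

The hierarchical Bayesian fit lives in :mod:`cogeffort.hddm`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .exceptions import ConfigError, FitError, InsufficientDataError

__all__ = [
    "HR",
    "LR",
    "DDMParams",
    "DDMFit",
    "RecoveryTruthConfig",
    "RecoveryReport",
    "choice_probability",
    "fpt_density",
    "fpt_cdf_grid",
    "mean_decision_time",
    "simulate_ddm",
    "loglik",
    "fit_mle",
    "inclusion_filter",
    "compare_group_parameters",
    "parameter_recovery",
]

HR = "HR"
LR = "LR"

#: per-trial log-likelihood floor for latencies at or below t0
LOGLIK_FLOOR = -1e10

#: box bounds for maximum-likelihood fitting
MLE_BOUNDS = {"v": (-5.0, 5.0), "a": (0.1, 5.0), "w": (0.05, 0.95)}

#: minimum trials for a per-participant maximum-likelihood fit
MIN_TRIALS_MLE = 8


@dataclass(frozen=True)
class DDMParams:
    """Drift rate, boundary separation, relative starting point, non-decision time."""

    v: float
    a: float
    w: float
    t0: float

    def __post_init__(self):
        if not all(np.isfinite([self.v, self.a, self.w, self.t0])):
            raise ValueError("diffusion parameters must be finite")
        if self.a <= 0:
            raise ValueError(f"boundary separation must be > 0, got {self.a}")
        if not 0.0 < self.w < 1.0:
            raise ValueError(f"starting point must be in (0, 1), got {self.w}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t0}")

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.a, self.w, self.t0])


@dataclass
class DDMFit:
    """Point estimate (or posterior mean) of one participant's parameters."""

    params: DDMParams
    loglik: float
    n_trials_used: int
    converged: bool
    participant_id: object = None
    posterior_summaries: dict | None = None


# ---------------------------------------------------------------------------
# closed-form choice probability
# ---------------------------------------------------------------------------

def choice_probability(params: DDMParams) -> float:
    """Probability of absorption at the upper (HR) boundary.

    ``P(HR) = (1 - exp(-2 v a w)) / (1 - exp(-2 v a))`` for ``v != 0`` and
    ``w`` in the driftless limit; the implementation switches to a series
    near ``v = 0`` for numerical stability.
    """
    x = 2.0 * params.v * params.a
    w = params.w
    if abs(x) < 1e-6:
        # (1 - e^{-xw}) / (1 - e^{-x}) = w * (1 + (1 - w) x / 2 + O(x^2))
        return w * (1.0 + (1.0 - w) * x / 2.0)
    return float(np.expm1(-x * w) / np.expm1(-x))


# ---------------------------------------------------------------------------
# first-passage-time density (small-time / large-time series)
# ---------------------------------------------------------------------------

def _f_unit_lower(u: np.ndarray, w: float, err: float) -> np.ndarray:
    """Density of first passage through the lower of unit-separation
    boundaries for a driftless unit diffusion started at fraction ``w``,
    in normalised time ``u = t / a**2``.

    Chooses between the small-time and large-time expansions per element by
    comparing the number of terms each needs for truncation error ``err``.
    """
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    pos = u > 0
    if not np.any(pos):
        return out
    up = u[pos]

    # terms needed by each expansion (standard truncation bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * up) * err
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * up * np.log(np.maximum(arg_s, 1e-300)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(up) + 1.0)
        arg_l = np.pi * up * err
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg_l, 1e-300)), 0.0) / (np.pi**2 * up)),
            0.0,
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(up)))

    use_small = ks < kl
    res = np.empty_like(up)

    if np.any(use_small):
        us = up[use_small]
        K = int(np.ceil(ks[use_small].max()))
        ks_range = np.arange(-((K - 1) // 2), ((K - 1) // 2) + 2)
        nodes = w + 2.0 * ks_range  # (m,)
        expo = -(nodes[None, :] ** 2) / (2.0 * us[:, None])
        terms = nodes[None, :] * np.exp(expo)
        res[use_small] = terms.sum(axis=1) / np.sqrt(2.0 * np.pi * us**3)

    if np.any(~use_small):
        ul = up[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        kk = np.arange(1, K + 1, dtype=float)
        terms = kk[None, :] * np.exp(-(kk[None, :] ** 2) * np.pi**2 * ul[:, None] / 2.0)
        terms = terms * np.sin(kk[None, :] * np.pi * w)
        res[~use_small] = np.pi * terms.sum(axis=1)

    out[pos] = np.maximum(res, 0.0)
    return out


def fpt_density(t, params: DDMParams, boundary: str = HR, err: float = 1e-10):
    """Defective first-passage density of the response latency ``t``.

    Returns the density of absorption at ``boundary`` evaluated at latency
    ``t`` (which includes ``t0``); 0 for ``t <= t0``.  Integrating over
    ``t`` gives the boundary's choice probability.  Reflection symmetry
    holds: parameters ``(v, a, w)`` at HR equal ``(-v, a, 1-w)`` at LR.
    """
    if err <= 0:
        raise ConfigError("series truncation tolerance must be positive")
    if boundary not in (HR, LR):
        raise ValueError(f"boundary must be {HR!r} or {LR!r}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if boundary == HR:
        v, w = -params.v, 1.0 - params.w
    else:
        v, w = params.v, params.w
    a = params.a
    dt = t_arr - params.t0
    out = np.zeros_like(dt)
    pos = dt > 0
    if np.any(pos):
        u = dt[pos] / a**2
        f1 = _f_unit_lower(u, w, err)
        out[pos] = f1 / a**2 * np.exp(-v * a * w - v**2 * dt[pos] / 2.0)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out[0])
    return out


def fpt_cdf_grid(
    params: DDMParams, boundary: str = HR, n_grid: int = 4096, tail: float = 1e-9
):
    """Dense grid of the defective CDF at one boundary.

    Returns ``(t, cdf)`` where ``cdf[i]`` approximates the probability of
    absorbing at ``boundary`` by latency ``t[i]``; ``cdf[-1]`` approaches
    the boundary's choice probability.  The grid is quadratically spaced
    (dense near onset) and extended until the remaining mass is below
    ``tail``.
    """
    p_b = choice_probability(params) if boundary == HR else 1.0 - choice_probability(params)
    # initial horizon: generous multiple of the driftless mean passage time
    span = params.a**2 + 4.0 * params.a / max(abs(params.v), 0.25)
    for _ in range(12):
        s = np.linspace(0.0, 1.0, n_grid) ** 2 * span
        t = params.t0 + s
        dens = fpt_density(t, params, boundary)
        cdf = integrate.cumulative_trapezoid(dens, t, initial=0.0)
        if p_b - cdf[-1] < max(tail, 1e-12) or cdf[-1] > p_b:
            break
        span *= 2.0
    return t, np.minimum(cdf, p_b)


def mean_decision_time(params: DDMParams) -> float:
    """Mean latency ``E[t]`` (including ``t0``) by quadrature over both
    boundaries' densities."""
    t, cdf_hr = fpt_cdf_grid(params, HR)
    dens = fpt_density(t, params, HR) + fpt_density(t, params, LR)
    total = integrate.trapezoid(dens, t)
    return float(integrate.trapezoid(t * dens, t) / total)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_ddm(
    params: DDMParams,
    n: int,
    rng: np.random.Generator,
    method: str = "euler",
    dt: float = 1e-4,
    max_time: float = 300.0,
):
    """Draw ``n`` independent (choice, latency) pairs.

    Returns ``(is_hr, latency)`` arrays; ``is_hr`` is True for upper-boundary
    (HR) absorptions and latencies include ``t0`` (strictly greater than it).

    ``method="euler"`` (default) integrates the diffusion at step ``dt``
    with a Brownian-bridge correction for within-step boundary crossings,
    which removes the O(sqrt(dt)) first-passage bias of the naive scheme.
    ``method="inverse_cdf"`` samples the boundary from the closed-form
    choice probability and the conditional latency by numerically inverting
    the series-density CDF; it is exact up to quadrature error and much
    faster, and is what the cohort generator and recovery harness use.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if method == "euler":
        return _simulate_euler(params, n, rng, dt=dt, max_time=max_time)
    if method == "inverse_cdf":
        return _simulate_invcdf(params, n, rng)
    raise ValueError(f"unknown simulation method {method!r}")


def _simulate_euler(params, n, rng, dt=1e-4, max_time=300.0):
    v, a, w, t0 = params.v, params.a, params.w, params.t0
    sqrt_dt = math.sqrt(dt)
    is_hr = np.zeros(n, dtype=bool)
    rt = np.full(n, np.nan)
    x = np.full(n, a * w)
    base_t = np.zeros(n)
    active = np.arange(n)

    while active.size:
        m = active.size
        block = max(16, min(512, int(4e6 / max(m, 1))))
        incr = rng.standard_normal((block, m)) * sqrt_dt + v * dt
        pos = x[active][None, :] + np.cumsum(incr, axis=0)
        prev = np.vstack([x[active][None, :], pos[:-1]])

        hit_up = pos >= a
        hit_lo = pos <= 0.0
        inside = ~(hit_up | hit_lo)
        # Brownian-bridge within-step crossing probabilities
        with np.errstate(over="ignore"):
            p_up = np.exp(-2.0 * (a - prev) * (a - pos) / dt)
            p_lo = np.exp(-2.0 * prev * pos / dt)
        u1 = rng.random((block, m))
        u2 = rng.random((block, m))
        bridge_up = inside & (u1 < p_up)
        bridge_lo = inside & ~bridge_up & (u2 < p_lo)

        event = hit_up | hit_lo | bridge_up | bridge_lo
        any_event = event.any(axis=0)
        first = event.argmax(axis=0)
        cols = np.nonzero(any_event)[0]
        rows = first[cols]
        gids = active[cols]
        is_hr[gids] = hit_up[rows, cols] | bridge_up[rows, cols]
        rt[gids] = t0 + base_t[gids] + (rows + 1) * dt

        keep = ~any_event
        surv = active[keep]
        x[surv] = pos[-1, keep]
        base_t[surv] += block * dt
        active = surv
        if active.size and base_t[active].min() > max_time:
            # pathological parameters: absorb remaining paths at the nearer
            # boundary so the call terminates
            is_hr[active] = x[active] >= a / 2.0
            rt[active] = t0 + base_t[active]
            break
    return is_hr, rt


def _invert_cdf(t_grid, cdf, u, rng_jitter=None):
    total = cdf[-1]
    cdf = np.maximum.accumulate(cdf)
    # strictly increasing support for interpolation
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    return np.interp(u * total, cdf[keep], t_grid[keep])


def _simulate_invcdf(params, n, rng):
    p_hr = choice_probability(params)
    is_hr = rng.random(n) < p_hr
    rt = np.empty(n)
    for boundary, mask in ((HR, is_hr), (LR, ~is_hr)):
        k = int(mask.sum())
        if k == 0:
            continue
        t_grid, cdf = fpt_cdf_grid(params, boundary)
        if cdf[-1] <= 0:
            rt[mask] = params.t0 + 1e-6
            continue
        rt[mask] = _invert_cdf(t_grid, cdf, rng.random(k))
    rt = np.maximum(rt, params.t0 + 1e-9)
    return is_hr, rt


# ---------------------------------------------------------------------------
# likelihood and maximum-likelihood fitting
# ---------------------------------------------------------------------------

def loglik(params: DDMParams, is_hr: np.ndarray, latency: np.ndarray) -> float:
    """Joint log-likelihood of choices and latencies; latencies at or below
    ``t0`` contribute the floor value instead of ``-inf``."""
    is_hr = np.asarray(is_hr, dtype=bool)
    latency = np.asarray(latency, dtype=float)
    total = 0.0
    for boundary, mask in ((HR, is_hr), (LR, ~is_hr)):
        if not mask.any():
            continue
        dens = fpt_density(latency[mask], params, boundary)
        dens = np.asarray(dens, dtype=float)
        bad = dens <= 0
        good_sum = float(np.sum(np.log(dens[~bad]))) if np.any(~bad) else 0.0
        total += good_sum + float(bad.sum()) * LOGLIK_FLOOR
    return total


def _heuristic_start(is_hr, latency):
    p = float(np.clip(np.mean(is_hr), 0.05, 0.95))
    t0 = 0.9 * float(np.min(latency))
    return np.array([2.0 * (p - 0.5), 1.5, p, max(t0, 0.02)])


def fit_mle(
    is_hr: np.ndarray,
    latency: np.ndarray,
    n_starts: int = 5,
    seed: int | np.random.Generator | None = 0,
    participant_id=None,
) -> DDMFit:
    """Maximum-likelihood fit of (v, a, w, t0) to one participant's trials.

    Multi-start L-BFGS-B within the box ``v in [-5, 5]``, ``a in (0.1, 5]``,
    ``w in [0.05, 0.95]``, ``t0 in [0.01, 0.99 * min latency]``; the best
    local optimum is returned with a ``converged`` flag from the optimiser.
    """
    is_hr = np.asarray(is_hr, dtype=bool)
    latency = np.asarray(latency, dtype=float)
    if len(is_hr) != len(latency):
        raise ValueError("choice and latency arrays must have equal length")
    if len(is_hr) < MIN_TRIALS_MLE:
        raise InsufficientDataError(
            f"need at least {MIN_TRIALS_MLE} trials, got {len(is_hr)}"
        )
    if np.any(latency <= 0):
        raise ValueError("latencies must be positive")
    if is_hr.all() or (~is_hr).all():
        raise FitError(
            "all choices at one boundary: starting point and boundary "
            "separation are unidentifiable"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t0_hi = max(0.99 * float(np.min(latency)), 0.0101)
    bounds = [MLE_BOUNDS["v"], MLE_BOUNDS["a"], MLE_BOUNDS["w"], (0.01, t0_hi)]

    def nll(x):
        try:
            p = DDMParams(*x)
        except ValueError:
            return -LOGLIK_FLOOR
        return -loglik(p, is_hr, latency)

    starts = [_heuristic_start(is_hr, latency)]
    starts[0][3] = min(starts[0][3], t0_hi)
    for _ in range(max(n_starts - 1, 0)):
        starts.append(
            np.array(
                [
                    rng.uniform(-2.5, 2.5),
                    rng.uniform(0.6, 3.0),
                    rng.uniform(0.2, 0.8),
                    rng.uniform(0.01, t0_hi),
                ]
            )
        )

    best = None
    best_ok = False
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
            best_ok = bool(res.success)
    params = DDMParams(*best.x)
    return DDMFit(
        params=params,
        loglik=-float(best.fun),
        n_trials_used=len(is_hr),
        converged=best_ok,
        participant_id=participant_id,
    )


# ---------------------------------------------------------------------------
# inclusion filter
# ---------------------------------------------------------------------------

def inclusion_filter(choice_trials: pd.DataFrame):
    """Participants eligible for diffusion modelling, plus an exclusion log.

    Keeps participants with at least one correct HR trial, at least one
    correct LR trial, and at least four choices of each type.  The log
    records the first failed criterion per excluded participant.
    """
    eligible = []
    log_rows = []
    for pid, grp in choice_trials.groupby("participant_id", sort=True):
        hr = grp["choice"] == HR
        n_hr, n_lr = int(hr.sum()), int((~hr).sum())
        correct = grp["performed_correct"].astype(bool)
        reason = None
        if n_hr < 4:
            reason = "fewer_than_4_hr_choices"
        elif n_lr < 4:
            reason = "fewer_than_4_lr_choices"
        elif not bool((hr & correct).any()):
            reason = "no_correct_hr_trial"
        elif not bool((~hr & correct).any()):
            reason = "no_correct_lr_trial"
        if reason is None:
            eligible.append(pid)
        else:
            log_rows.append({"participant_id": pid, "reason": reason})
    return eligible, pd.DataFrame(log_rows, columns=["participant_id", "reason"])


def compare_group_parameters(fits: list[DDMFit] | pd.DataFrame, assignments: pd.DataFrame):
    """Welch t-tests (Bonferroni family of 4, Cohen's d) comparing each
    diffusion parameter between the high- and low-effort groups."""
    from .stats import welch_t_test  # local import; stats does not import ddm

    if isinstance(fits, pd.DataFrame):
        df = fits.copy()
    else:
        df = pd.DataFrame(
            {
                "participant_id": [f.participant_id for f in fits],
                "v": [f.params.v for f in fits],
                "a": [f.params.a for f in fits],
                "w": [f.params.w for f in fits],
                "t0": [f.params.t0 for f in fits],
            }
        )
    merged = df.merge(assignments[["participant_id", "group"]], on="participant_id")
    hi = merged[merged["group"] == "high_effort"]
    lo = merged[merged["group"] == "low_effort"]
    if len(hi) < 2 or len(lo) < 2:
        raise InsufficientDataError("need at least two participants per effort group")
    results = {}
    for name in ("v", "a", "w", "t0"):
        results[name] = welch_t_test(
            hi[name].to_numpy(), lo[name].to_numpy(), family_size=4, measure=name
        )
    return results


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryTruthConfig:
    """Ranges the true per-participant parameters are drawn from (uniform;
    drift gets a random sign).  Degenerate zero-spread ranges are rejected:
    recovery correlations are undefined without variation in the truth."""

    v_magnitude: tuple[float, float] = (0.8, 2.2)
    a_range: tuple[float, float] = (1.0, 2.2)
    w_range: tuple[float, float] = (0.35, 0.75)
    t0_range: tuple[float, float] = (0.2, 0.5)
    p_positive_drift: float = 0.5

    def validate(self):
        for name in ("v_magnitude", "a_range", "w_range", "t0_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(
                    f"{name} must have strictly increasing bounds (zero-spread "
                    "truth makes recovery correlations undefined)"
                )
        if not 0.0 <= self.p_positive_drift <= 1.0:
            raise ConfigError("p_positive_drift must be a probability")

    def sample(self, rng: np.random.Generator) -> DDMParams:
        v = rng.uniform(*self.v_magnitude)
        if rng.random() >= self.p_positive_drift:
            v = -v
        return DDMParams(
            v=v,
            a=rng.uniform(*self.a_range),
            w=rng.uniform(*self.w_range),
            t0=rng.uniform(*self.t0_range),
        )


#: below this many trials per participant the report flags the regime as
#: low-information (the study's own 30-trial scale falls well under it)
LOW_INFORMATION_TRIALS = 100


@dataclass
class RecoveryReport:
    """Per-parameter recovery quality from a simulate-and-refit experiment."""

    n_participants: int
    trials_per_participant: int
    seed: int | None
    bias: dict[str, float]
    rmse: dict[str, float]
    correlation: dict[str, float]
    pooled_correlation: float
    low_information: bool
    truth: pd.DataFrame = field(repr=False)
    estimates: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "trials_per_participant": self.trials_per_participant,
            "seed": self.seed,
            "bias": self.bias,
            "rmse": self.rmse,
            "correlation": self.correlation,
            "pooled_correlation": self.pooled_correlation,
            "low_information": self.low_information,
        }


def parameter_recovery(
    truth_config: RecoveryTruthConfig,
    n_participants: int,
    trials_per_participant: int,
    rng: np.random.Generator | int,
    n_starts: int = 3,
    sim_method: str = "inverse_cdf",
) -> RecoveryReport:
    """Simulate each participant at known parameters, refit by maximum
    likelihood, and report per-parameter bias, RMSE and truth-estimate
    correlation (plus a pooled correlation over z-scored parameter vectors).
    """
    truth_config.validate()
    if trials_per_participant < MIN_TRIALS_MLE:
        raise InsufficientDataError(
            f"trials_per_participant must be >= {MIN_TRIALS_MLE}"
        )
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = int(rng)
        rng = np.random.default_rng(seed)

    names = ("v", "a", "w", "t0")
    truths, ests = [], []
    for i in range(n_participants):
        true = truth_config.sample(rng)
        while True:
            is_hr, rt = simulate_ddm(true, trials_per_participant, rng, method=sim_method)
            if 0 < is_hr.sum() < len(is_hr):
                break
        fit = fit_mle(is_hr, rt, n_starts=n_starts, seed=rng, participant_id=i)
        truths.append(true.as_array())
        ests.append(fit.params.as_array())
    truth = pd.DataFrame(truths, columns=names)
    est = pd.DataFrame(ests, columns=names)

    bias = {n: float((est[n] - truth[n]).mean()) for n in names}
    rmse = {n: float(np.sqrt(((est[n] - truth[n]) ** 2).mean())) for n in names}
    corr = {n: float(np.corrcoef(truth[n], est[n])[0, 1]) for n in names}

    zt = (truth - truth.mean()) / truth.std(ddof=0)
    ze = (est - est.mean()) / est.std(ddof=0)
    pooled = float(np.corrcoef(zt.to_numpy().ravel(), ze.to_numpy().ravel())[0, 1])

    low_info = trials_per_participant < LOW_INFORMATION_TRIALS or min(corr.values()) < 0.8
    return RecoveryReport(
        n_participants=n_participants,
        trials_per_participant=trials_per_participant,
        seed=seed,
        bias=bias,
        rmse=rmse,
        correlation=corr,
        pooled_correlation=pooled,
        low_information=bool(low_info),
        truth=truth,
        estimates=est,
    )
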