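"""Simulation studies validating the pipeline against its own design.

These are the package's self-checks: density calibration of the diffusion
machinery, simulator-versus-density agreement, maximum-likelihood recovery
curves across trial budgets, pipeline-level recovery of the
capacity -> effort-preference effect with null trait effects, and the
type-I error of the mixed ANOVA under the null.  They are exercised by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

from .capacity import k_table
from .cohort import generate_cohort
from .config import CohortConfig
from .ddm import (
    HR,
    LR,
    DDMParams,
    RecoveryTruthConfig,
    choice_probability,
    fpt_cdf_grid,
    fpt_density,
    parameter_recovery,
    simulate_ddm,
)
from .stats import apply_exclusions, classify_all, fit_group_logistic, mixed_anova_2x2_core

__all__ = [
    "random_ddm_params",
    "density_validation",
    "simulator_density_ks",
    "recovery_curve",
    "capacity_effect_replicates",
    "anova_null_type_one_error",
]


def random_ddm_params(rng: np.random.Generator, v_span: float = 3.0) -> DDMParams:
    """Random parameter draw over the regime the task occupies."""
    return DDMParams(
        v=rng.uniform(-v_span, v_span),
        a=rng.uniform(0.8, 2.5),
        w=rng.uniform(0.2, 0.8),
        t0=rng.uniform(0.1, 0.5),
    )


def density_validation(n_draws: int, seed: int) -> pd.DataFrame:
    """Quadrature checks of the first-passage density for random draws.

    For each draw reports the total absorption probability (should be 1),
    the gap between the integrated HR density and the closed-form choice
    probability, and the maximum pointwise reflection-symmetry violation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_draws):
        p = random_ddm_params(rng)
        q_hr = integrate.quad(lambda t: fpt_density(t, p, HR), p.t0, np.inf, limit=300)[0]
        q_lr = integrate.quad(lambda t: fpt_density(t, p, LR), p.t0, np.inf, limit=300)[0]
        mirror = DDMParams(-p.v, p.a, 1 - p.w, p.t0)
        t = p.t0 + rng.uniform(0.01, 3.0, size=64)
        d1 = np.asarray(fpt_density(t, p, HR))
        d2 = np.asarray(fpt_density(t, mirror, LR))
        denom = np.maximum(np.abs(d1), 1e-300)
        rows.append(
            {
                "total_mass_error": abs(q_hr + q_lr - 1.0),
                "choice_prob_error": abs(q_hr - choice_probability(p)),
                "reflection_error": float(np.max(np.abs(d1 - d2) / denom)),
            }
        )
    return pd.DataFrame(rows)


def mixture_cdf(params: DDMParams):
    """Grid CDF of the total latency pooled over both boundaries."""
    t_hr, c_hr = fpt_cdf_grid(params, HR)
    t_lr, c_lr = fpt_cdf_grid(params, LR)
    grid = np.union1d(t_hr, t_lr)
    return grid, np.interp(grid, t_hr, c_hr) + np.interp(grid, t_lr, c_lr)


def simulator_density_ks(
    n_sets: int, n: int, seed: int, method: str = "euler"
) -> pd.DataFrame:
    """KS distance between simulated latencies and the density-implied CDF
    for random parameter sets (latencies pooled over both boundaries)."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_sets):
        p = random_ddm_params(rng, v_span=2.5)
        _, rt = simulate_ddm(p, n, rng, method=method)
        grid, F = mixture_cdf(p)
        srt = np.sort(rt)
        Fs = np.interp(srt, grid, F)
        i = np.arange(1, n + 1)
        ks = max(float(np.max(i / n - Fs)), float(np.max(Fs - (i - 1) / n)))
        rows.append({"v": p.v, "a": p.a, "w": p.w, "t0": p.t0, "ks": ks})
    return pd.DataFrame(rows)


def recovery_curve(
    trial_counts, n_participants: int, seed: int, truth: RecoveryTruthConfig | None = None
):
    """Parameter-recovery reports across a ladder of trial budgets."""
    truth = truth or RecoveryTruthConfig()
    return {
        n_trials: parameter_recovery(
            truth, n_participants, n_trials, rng=seed + i
        )
        for i, n_trials in enumerate(trial_counts)
    }


def capacity_effect_replicates(
    n_replicates: int,
    seed: int,
    n_participants: int = 429,
    base_config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Pipeline-level recovery of the capacity effect on effort preference.

    Each replicate simulates a full cohort (capacity coupled to the
    diffusion starting point, traits causally inert), applies the
    exclusions, estimates whole-display K at set size 4, classifies effort
    groups and fits the binomial logistic regression.  Returns one row per
    replicate with the K coefficient, its p-value, and the trait p-values
    (whose rejection rate estimates the type-I error).
    """
    base = base_config or CohortConfig()
    rows = []
    for rep in range(n_replicates):
        cfg = dataclasses.replace(
            base, n_participants=n_participants, seed=(seed * 100003 + rep) % (2**31)
        )
        cohort = generate_cohort(cfg)
        kept, _ = apply_exclusions(cohort)
        k4 = k_table(kept.detection_trials, set_sizes=(4,))
        table = kept.participants.merge(
            k4[["participant_id", "k"]], on="participant_id"
        ).merge(classify_all(kept.choice_trials), on="participant_id")
        res = fit_group_logistic(table)
        rows.append(
            {
                "replicate": rep,
                "n_kept": len(table),
                "beta_k": res.coef["k"],
                "p_k": res.pvalues["k"],
                "odds_ratio_k": res.odds_ratios["k"],
                "p_bdi": res.pvalues["bdi_prop"],
                "p_pss": res.pvalues["pss"],
                "p_anticipation": res.pvalues["anticipation"],
            }
        )
    return pd.DataFrame(rows)


def anova_null_type_one_error(
    n_replicates: int, seed: int, n1: int = 40, n2: int = 30, alpha: float = 0.05
) -> dict[str, float]:
    """Rejection rates of each mixed-ANOVA effect under pure-noise data."""
    rng = np.random.default_rng(seed)
    N = n1 + n2
    g = np.arange(N) < n1
    y1 = rng.standard_normal((n_replicates, N))
    y2 = rng.standard_normal((n_replicates, N))
    core = mixed_anova_2x2_core(y1, y2, g)
    dfe = core["df_error"]
    out = {}
    for effect in ("group", "trial_type", "interaction"):
        p = sps.f.sf(core[f"F_{effect}"], 1, dfe)
        out[effect] = float(np.mean(p < alpha))
    return out
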