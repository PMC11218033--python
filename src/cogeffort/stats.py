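"""Exclusions, effort phenotyping, and the cohort-level statistical battery.

Implements the analysis pipeline applied to a cohort table: compliance
exclusions, the >70% high-reward-choice phenotype split, Welch t-tests with
Bonferroni correction, trait/capacity correlations, binomial logistic and
linear regressions of effort preference, 2x2 within-between ANOVAs with
generalized eta squared and Greenhouse-Geisser correction, random-intercept
multilevel models, and the lagged-performance follow-up regression.

Conventions: Cohen's d uses the pooled SD; degrees of freedom are
Welch-Satterthwaite throughout; ANOVA sums of squares are Type III with
sum-to-zero contrasts; the Greenhouse-Geisser correction is the identity for
a two-level within factor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import FitError, InsufficientDataError

__all__ = [
    "EffortAssignment",
    "TTestResult",
    "RegressionResult",
    "AnovaResult",
    "welch_t_test",
    "apply_exclusions",
    "classify_effort_group",
    "classify_all",
    "summarize_by_group",
    "pairwise_t_tests",
    "correlation_matrix",
    "fit_group_logistic",
    "fit_proportion_linear",
    "anova_mixed_2x2",
    "fit_multilevel",
    "lagged_performance_regression",
]

EXCLUSION_REASONS = (
    "incomplete_survey",
    "incomplete_mid",
    "repeated_task",
    "slow_choice_gt30s",
    "chance_choice_accuracy",
)

#: strict threshold on the proportion of HR choices for the high-effort group
HIGH_EFFORT_THRESHOLD = 0.70


@dataclass(frozen=True)
class EffortAssignment:
    participant_id: object
    proportion_hr: float
    group: str  # "high_effort" | "low_effort"


@dataclass
class TTestResult:
    measure: str
    t: float
    df: float
    p_raw: float
    p_adjusted: float
    cohens_d: float
    family_size: int

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class RegressionResult:
    model: str
    terms: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    stat: dict[str, float]
    pvalues: dict[str, float]
    odds_ratios: dict[str, float] | None = None
    fit_stats: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class AnovaResult:
    effects: list[dict]  # name, F, df1, df2, p, p_gg, ges
    gg_epsilon: float
    n_participants: int
    n_dropped: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self):
        return dataclasses.asdict(self)

    def effect(self, name: str) -> dict:
        for e in self.effects:
            if e["name"] == name:
                return e
        raise KeyError(name)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def welch_t_test(x, y, family_size: int = 1, measure: str = "") -> TTestResult:
    """Unequal-variance t-test with Welch-Satterthwaite df, Bonferroni
    adjustment over ``family_size`` tests, and pooled-SD Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    if vx == 0 and vy == 0:
        t, df, p = 0.0, float(nx + ny - 2), 1.0
    else:
        res = sps.ttest_ind(x, y, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    pooled_sd = np.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    d = 0.0 if pooled_sd == 0 else float((x.mean() - y.mean()) / pooled_sd)
    return TTestResult(
        measure=measure,
        t=t,
        df=float(df),
        p_raw=p,
        p_adjusted=min(1.0, family_size * p),
        cohens_d=d,
        family_size=family_size,
    )


# ---------------------------------------------------------------------------
# exclusions and phenotype
# ---------------------------------------------------------------------------

def apply_exclusions(cohort):
    """Drop non-compliant participants and return (kept cohort, exclusion log).

    Rules in order of application (first failure is the recorded reason):
    incomplete survey, incomplete incentive-rating task, repeated task, any
    single choice latency strictly above 30 s, choice-phase accuracy at or
    below chance (0.50).  A latency of exactly 30 s is kept; accuracy of
    exactly 0.50 is excluded.
    """
    participants = cohort.participants
    choices = cohort.choice_trials
    max_lat = choices.groupby("participant_id")["choice_latency"].max()
    acc = choices.groupby("participant_id")["performed_correct"].mean()

    reasons = {}
    for _, row in participants.iterrows():
        pid = row["participant_id"]
        if "completed_survey" in row.index and not row["completed_survey"]:
            reasons[pid] = "incomplete_survey"
        elif "completed_mid" in row.index and not row["completed_mid"]:
            reasons[pid] = "incomplete_mid"
        elif "repeated_task" in row.index and row["repeated_task"]:
            reasons[pid] = "repeated_task"
        elif max_lat.get(pid, 0.0) > 30.0:
            reasons[pid] = "slow_choice_gt30s"
        elif acc.get(pid, 1.0) <= 0.50:
            reasons[pid] = "chance_choice_accuracy"

    log = pd.DataFrame(
        [{"participant_id": p, "reason": r} for p, r in reasons.items()],
        columns=["participant_id", "reason"],
    )
    keep = ~participants["participant_id"].isin(reasons)
    kept_ids = set(participants.loc[keep, "participant_id"])

    from .cohort import Cohort  # local import to avoid a cycle at load time

    kept = Cohort(
        participants=participants[keep].reset_index(drop=True),
        detection_trials=cohort.detection_trials[
            cohort.detection_trials["participant_id"].isin(kept_ids)
        ].reset_index(drop=True),
        choice_trials=choices[choices["participant_id"].isin(kept_ids)].reset_index(
            drop=True
        ),
        mid_ratings=cohort.mid_ratings[
            cohort.mid_ratings["participant_id"].isin(kept_ids)
        ].reset_index(drop=True),
        config=cohort.config,
    )
    return kept, log


def classify_effort_group(choice_trials: pd.DataFrame) -> EffortAssignment:
    """Phenotype one participant: proportion of HR choices strictly above
    0.70 puts them in the high-effort group, otherwise low-effort."""
    if len(choice_trials) == 0:
        raise InsufficientDataError("no choice trials to classify")
    pids = choice_trials["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("classify_effort_group expects a single participant")
    prop = float((choice_trials["choice"] == "HR").mean())
    group = "high_effort" if prop > HIGH_EFFORT_THRESHOLD else "low_effort"
    return EffortAssignment(participant_id=pids[0], proportion_hr=prop, group=group)


def classify_all(choice_trials: pd.DataFrame) -> pd.DataFrame:
    """Tidy assignment table for every participant in a choice-trial table."""
    rows = [
        dataclasses.asdict(classify_effort_group(grp))
        for _, grp in choice_trials.groupby("participant_id", sort=True)
    ]
    return pd.DataFrame(rows, columns=["participant_id", "proportion_hr", "group"])


def summarize_by_group(choice_trials: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of per-participant accuracy and choice latency in each
    (effort group x trial type) cell; SD is NaN for single-participant cells
    and participants contribute nothing to trial types they never chose."""
    per = (
        choice_trials.groupby(["participant_id", "choice"])
        .agg(accuracy=("performed_correct", "mean"), latency=("choice_latency", "mean"))
        .reset_index()
        .merge(assignments[["participant_id", "group"]], on="participant_id")
    )
    out = (
        per.groupby(["group", "choice"])
        .agg(
            mean_accuracy=("accuracy", "mean"),
            sd_accuracy=("accuracy", lambda s: s.std(ddof=1)),
            mean_latency=("latency", "mean"),
            sd_latency=("latency", lambda s: s.std(ddof=1)),
            n=("accuracy", "size"),
        )
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# univariate battery
# ---------------------------------------------------------------------------

def pairwise_t_tests(
    participants: pd.DataFrame,
    measures=("bdi_prop", "pss", "dars", "anticipation"),
    family_size: int | None = None,
) -> dict[str, TTestResult]:
    """Female-vs-male Welch t-tests on each trait measure, Bonferroni
    corrected over the family (participants of other sexes are excluded,
    mirroring the under-powered-cell rule)."""
    family = family_size if family_size is not None else len(measures)
    f = participants[participants["sex"] == "female"]
    m = participants[participants["sex"] == "male"]
    return {
        meas: welch_t_test(f[meas], m[meas], family_size=family, measure=meas)
        for meas in measures
    }


def correlation_matrix(
    table: pd.DataFrame, columns=("bdi_prop", "pss", "anticipation", "k")
) -> pd.DataFrame:
    """Pearson correlations with two-sided p-values for all column pairs.

    Returns a tidy frame ``var1, var2, r, p``; zero-variance columns yield
    NaN (undefined-flagged) entries.
    """
    if len(table) < 3:
        raise InsufficientDataError("need at least 3 participants")
    rows = []
    for i, c1 in enumerate(columns):
        for c2 in columns[i:]:
            x, y = table[c1].to_numpy(float), table[c2].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = float("nan"), float("nan")
            elif c1 == c2:
                r, p = 1.0, 0.0
            else:
                r, p = (float(v) for v in sps.pearsonr(x, y))
            rows.append({"var1": c1, "var2": c2, "r": r, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regressions of effort preference
# ---------------------------------------------------------------------------

_PREDICTORS = ["k", "bdi_prop", "pss", "anticipation"]


def _design(table: pd.DataFrame, include_sex: bool):
    cols = list(_PREDICTORS)
    X = table[cols].astype(float).copy()
    if include_sex:
        X.insert(0, "sex_male", (table["sex"] == "male").astype(float))
    return sm.add_constant(X)


def fit_group_logistic(table: pd.DataFrame, include_sex: bool = False) -> RegressionResult:
    """Binomial logistic regression of effort group (high = 1) on capacity
    and trait predictors; reports beta, SE, z, p and odds ratios e^beta.

    Complete separation is flagged (``converged=False``) rather than
    returning silent estimates.
    """
    y = (table["group"] == "high_effort").astype(int)
    if y.nunique() < 2:
        raise FitError("both effort groups must be present")
    X = _design(table, include_sex)
    converged = True
    notes: list[str] = []
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:  # perfect separation raises in statsmodels
        raise FitError(f"logistic fit failed: {exc}") from exc
    if np.any(np.abs(res.params) > 50) or np.any(res.bse > 1e3):
        converged = False
        notes.append("quasi-separation suspected: extreme coefficients or SEs")
    terms = list(X.columns)
    return RegressionResult(
        model="group_logistic",
        terms=terms,
        coef={t: float(res.params[t]) for t in terms},
        se={t: float(res.bse[t]) for t in terms},
        stat={t: float(res.tvalues[t]) for t in terms},
        pvalues={t: float(res.pvalues[t]) for t in terms},
        odds_ratios={t: float(np.exp(res.params[t])) for t in terms},
        fit_stats={"loglik": float(res.llf), "aic": float(res.aic), "bic": float(res.bic)},
        n_obs=int(res.nobs),
        converged=converged,
        notes=notes,
    )


def fit_proportion_linear(table: pd.DataFrame, include_sex: bool = False) -> RegressionResult:
    """Ordinary least squares of the HR-choice proportion on the same
    predictors as the logistic model."""
    if len(table) < 10:
        raise InsufficientDataError("need at least 10 participants")
    y = table["proportion_hr"].astype(float)
    X = _design(table, include_sex)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise FitError(f"rank-deficient design (collinear terms: {worst})")
    res = sm.OLS(y, X).fit()
    # a constant outcome has zero total sum of squares; report R^2 = 0
    r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 0.0
    r2_adj = float(res.rsquared_adj) if np.isfinite(res.rsquared_adj) else 0.0
    terms = list(X.columns)
    return RegressionResult(
        model="proportion_linear",
        terms=terms,
        coef={t: float(res.params[t]) for t in terms},
        se={t: float(res.bse[t]) for t in terms},
        stat={t: float(res.tvalues[t]) for t in terms},
        pvalues={t: float(res.pvalues[t]) for t in terms},
        fit_stats={
            "r2": r2,
            "r2_adj": r2_adj,
            "loglik": float(res.llf),
            "aic": float(res.aic),
            "bic": float(res.bic),
        },
        n_obs=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# 2x2 within-between ANOVA
# ---------------------------------------------------------------------------

def mixed_anova_2x2_core(y_level1, y_level2, in_group1):
    """Type III sums-of-squares core for a 2 (between) x 2 (within) design.

    ``y_level1``/``y_level2`` are per-participant cell means at the two
    within-factor levels, shape ``(..., N)``; ``in_group1`` is a boolean
    group mask of length ``N``.  Vectorised over leading axes so simulation
    studies can evaluate thousands of replicates in one call.  Returns a
    dict of SS terms plus F statistics.
    """
    y1 = np.asarray(y_level1, float)
    y2 = np.asarray(y_level2, float)
    g = np.asarray(in_group1, bool)
    n1, n2 = int(g.sum()), int((~g).sum())
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs at least 2 participants")
    N = n1 + n2
    m = (y1 + y2) / 2.0
    d = y1 - y2

    def gmeans(x):
        return x[..., g].mean(-1), x[..., ~g].mean(-1)

    m1, m2 = gmeans(m)
    d1, d2 = gmeans(d)
    ssw_m = ((m[..., g] - m1[..., None]) ** 2).sum(-1) + (
        (m[..., ~g] - m2[..., None]) ** 2
    ).sum(-1)
    ssw_d = ((d[..., g] - d1[..., None]) ** 2).sum(-1) + (
        (d[..., ~g] - d2[..., None]) ** 2
    ).sum(-1)

    # between-subject effects (on subject means, scaled to observation units)
    ss_group = 2.0 * n1 * n2 / N * (m1 - m2) ** 2
    ss_subj = 2.0 * ssw_m
    # within-subject effects (on subject differences); Type III intercept
    # uses the unweighted mean of group means (sum-to-zero contrasts)
    beta_g = (n1 * d1 - n2 * d2) / N  # slope of d ~ 0 + group(+1/-1)
    sse_nointercept = (d**2).sum(-1) - N * beta_g**2
    ss_trial = (sse_nointercept - ssw_d) / 2.0
    ss_inter = (n1 * n2 / N) * (d1 - d2) ** 2 / 2.0
    ss_err_within = ssw_d / 2.0

    df_err = N - 2
    out = {
        "ss_group": ss_group,
        "ss_subjects": ss_subj,
        "ss_trial_type": ss_trial,
        "ss_interaction": ss_inter,
        "ss_error_within": ss_err_within,
        "df_error": df_err,
        "F_group": ss_group / (ss_subj / df_err),
        "F_trial_type": ss_trial / (ss_err_within / df_err),
        "F_interaction": ss_inter / (ss_err_within / df_err),
    }
    return out


def anova_mixed_2x2(
    long: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
    within_col: str = "choice",
    subject_col: str = "participant_id",
) -> AnovaResult:
    """2x2 within-between ANOVA on per-participant cell means.

    Duplicate cells per participant are aggregated by the mean first (noted
    in the result); participants missing either within-factor cell are
    dropped, mirroring the reduced error df of the published design.
    Reports F, degrees of freedom, raw and Greenhouse-Geisser corrected p
    (identical here: a two-level within factor has one df, so the sphericity
    correction is the identity), and generalized eta squared.
    """
    notes = []
    cells = (
        long.groupby([subject_col, group_col, within_col])[value_col]
        .agg(["mean", "size"])
        .reset_index()
    )
    if (cells["size"] > 1).any():
        notes.append("duplicate cells aggregated by mean")
    wide = cells.pivot_table(
        index=[subject_col, group_col], columns=within_col, values="mean"
    )
    levels = sorted(long[within_col].unique())
    if len(levels) != 2:
        raise ValueError("within factor must have exactly two levels")
    n_total = wide.shape[0]
    wide = wide.dropna()
    n_dropped = n_total - wide.shape[0]
    groups = sorted(long[group_col].unique())
    if len(groups) != 2:
        raise ValueError("between factor must have exactly two levels")
    gmask = wide.index.get_level_values(group_col) == groups[0]
    core = mixed_anova_2x2_core(
        wide[levels[0]].to_numpy(), wide[levels[1]].to_numpy(), gmask
    )
    df_err = core["df_error"]
    denom_ges = core["ss_subjects"] + core["ss_error_within"]
    effects = []
    for name, key in (
        ("group", "group"),
        ("trial_type", "trial_type"),
        ("interaction", "interaction"),
    ):
        F = float(core[f"F_{key}"])
        p = float(sps.f.sf(F, 1, df_err))
        ss = float(core[f"ss_{key}"])
        effects.append(
            {
                "name": name,
                "F": F,
                "df1": 1,
                "df2": int(df_err),
                "p": p,
                "p_gg": p,  # epsilon = 1 for a 1-df within effect
                "ges": float(ss / (ss + denom_ges)),
            }
        )
    return AnovaResult(
        effects=effects,
        gg_epsilon=1.0,
        n_participants=int(wide.shape[0]),
        n_dropped=int(n_dropped),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# multilevel models
# ---------------------------------------------------------------------------

def fit_multilevel(
    long: pd.DataFrame,
    outcome: str,
    predictors=("sex_male", "k", "bdi_prop", "pss", "anticipation", "effort_level"),
) -> RegressionResult:
    """Linear mixed model with a random intercept per participant.

    ``outcome`` is a trial-level column (``performed_correct`` as 0/1
    accuracy, or ``choice_latency`` in seconds).  ``effort_level`` codes the
    chosen trial type as 1 = low-effort (LR), 0 = high-effort, so positive
    coefficients mean higher outcome on the easier trials.  Reports fixed
    effects, the random-intercept and residual SDs, and marginal /
    conditional R-squared (fixed-effects variance over total, and fixed plus
    random over total).
    """
    df = long.copy()
    if "effort_level" not in df.columns and "choice" in df.columns:
        df["effort_level"] = (df["choice"] == "LR").astype(float)
    if "sex_male" not in df.columns and "sex" in df.columns:
        df["sex_male"] = (df["sex"] == "male").astype(float)
    counts = df.groupby("participant_id").size()
    if (counts >= 2).sum() < 10:
        raise InsufficientDataError(
            "need >= 2 observations per participant for >= 10 participants"
        )
    y = df[outcome].astype(float)
    X = sm.add_constant(df[list(predictors)].astype(float))
    import warnings

    notes: list[str] = []
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell", "nm"):
            try:
                model = sm.MixedLM(y, X, groups=df["participant_id"])
                kwargs = {} if method is None else {"method": method}
                res = model.fit(reml=True, **kwargs)
                break
            except np.linalg.LinAlgError:
                res = None
    if res is None:
        # the random-intercept variance is numerically singular; fall back
        # to pooled OLS (the limiting model) and flag the fit
        ols = sm.OLS(y, X).fit()
        notes.append("singular fit: random-intercept variance at boundary; pooled OLS fallback")
        terms = list(X.columns)
        var_res = float(ols.mse_resid)
        var_f = float(np.var(X.to_numpy() @ ols.params.to_numpy()))
        total = var_f + var_res
        return RegressionResult(
            model=f"multilevel_{outcome}",
            terms=terms,
            coef={t: float(ols.params[t]) for t in terms},
            se={t: float(ols.bse[t]) for t in terms},
            stat={t: float(ols.tvalues[t]) for t in terms},
            pvalues={t: float(ols.pvalues[t]) for t in terms},
            fit_stats={
                "sd_intercept": 0.0,
                "sd_residual": float(np.sqrt(var_res)),
                "r2_marginal": var_f / total,
                "r2_conditional": var_f / total,
                "icc": 0.0,
            },
            n_obs=int(len(df)),
            converged=False,
            notes=notes,
        )
    var_re = float(np.asarray(res.cov_re)[0, 0])
    var_res = float(res.scale)
    fitted_fixed = X.to_numpy() @ res.fe_params.to_numpy()
    var_f = float(np.var(fitted_fixed))
    total = var_f + var_re + var_res
    converged = bool(res.converged)
    if var_re < 1e-10:
        notes.append("singular fit: random-intercept variance at boundary")
    terms = list(X.columns)
    return RegressionResult(
        model=f"multilevel_{outcome}",
        terms=terms,
        coef={t: float(res.fe_params[t]) for t in terms},
        se={t: float(res.bse_fe[t]) for t in terms},
        stat={t: float(res.tvalues[t]) for t in terms},
        pvalues={t: float(res.pvalues[t]) for t in terms},
        fit_stats={
            "sd_intercept": float(np.sqrt(max(var_re, 0.0))),
            "sd_residual": float(np.sqrt(var_res)),
            "r2_marginal": var_f / total,
            "r2_conditional": (var_f + var_re) / total,
            "icc": var_re / (var_re + var_res),
        },
        n_obs=int(len(df)),
        converged=converged,
        notes=notes,
    )


def lagged_performance_regression(choice_trials: pd.DataFrame, assignments: pd.DataFrame) -> RegressionResult:
    """Does performance on the previous choice trial predict the current one?

    Regression (OLS) of current-trial correctness on previous-trial
    correctness, effort group and trial type; the first trial of each
    participant has no lag and is dropped, and participants with fewer than
    two trials contribute nothing (their count is noted).
    """
    df = choice_trials.sort_values(["participant_id", "trial_index"]).copy()
    df["prev_correct"] = (
        df.groupby("participant_id")["performed_correct"].shift(1).astype(float)
    )
    counts = df.groupby("participant_id").size()
    n_single = int((counts < 2).sum())
    df = df.dropna(subset=["prev_correct"])
    df = df.merge(assignments[["participant_id", "group"]], on="participant_id")
    df["group_high"] = (df["group"] == "high_effort").astype(float)
    df["trial_hr"] = (df["choice"] == "HR").astype(float)
    y = df["performed_correct"].astype(float)
    X = sm.add_constant(df[["prev_correct", "group_high", "trial_hr"]])
    res = sm.OLS(y, X).fit()
    terms = list(X.columns)
    notes = [f"{n_single} single-trial participant(s) excluded"] if n_single else []
    return RegressionResult(
        model="lagged_performance",
        terms=terms,
        coef={t: float(res.params[t]) for t in terms},
        se={t: float(res.bse[t]) for t in terms},
        stat={t: float(res.tvalues[t]) for t in terms},
        pvalues={t: float(res.pvalues[t]) for t in terms},
        fit_stats={"r2": float(res.rsquared)},
        n_obs=int(res.nobs),
        notes=notes,
    )
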