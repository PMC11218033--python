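"""Synthetic cohort generator for the calibrated effort-choice study.

One simulated participant passes through four phases:

1. an 8-trial incentive-rating (monetary incentive delay) phase whose mean
   pre-trial excitement rating operationalises reward anticipation;
2. a 10-trial practice block (set sizes 2/4/6 in counts 4/4/2), never used
   for capacity estimation;
3. a 120-trial change-detection calibration phase, 30 trials per set size in
   {2, 4, 6, 8}, half change / half no-change per set size, in random order;
4. a 30-trial effort-choice phase where a Wiener diffusion at the
   participant's latent parameters selects the high-reward (HR, 10 points)
   or low-reward (LR, 1 point) option and a change-detection trial is then
   performed at the chosen set size (0 points if incorrect).

Change detection follows a single-parameter capacity mixture: with
probability ``min(k, N) / N`` the probed item is in memory and the response
is correct; otherwise the participant guesses "change" with the configured
guess rate.  Latent capacity is drawn independently of the traits, and feeds
choice behaviour only through a logistic shift of the diffusion starting
point (and optionally drift).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .capacity import calibration_criterion, running_k_estimate
from .config import TRAITS, CohortConfig
from .ddm import DDMParams, simulate_ddm
from .exceptions import ConfigError, CriterionUndefinedError, ParseError

__all__ = [
    "Cohort",
    "generate_profiles",
    "simulate_detection_response",
    "generate_calibration_phase",
    "generate_choice_phase",
    "generate_mid_phase",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

PARTICIPANT_COLUMNS = [
    "participant_id", "sex", "age", "bdi_prop", "pss", "dars", "anticipation",
    "k_true", "v_true", "a_true", "w_true", "t0_true",
    "completed_survey", "completed_mid", "repeated_task",
]
DETECTION_COLUMNS = [
    "participant_id", "phase", "trial_index", "set_size", "is_change",
    "response_change", "correct", "rt",
]
CHOICE_COLUMNS = [
    "participant_id", "trial_index", "lr_set_size", "hr_set_size", "choice",
    "choice_latency", "performed_set_size", "performed_correct", "points",
]
MID_COLUMNS = ["participant_id", "trial_index", "rating"]

#: trait truncation boxes (scores cannot leave their scales)
_TRAIT_BOUNDS = {
    "bdi_prop": (0.0, 1.0),
    "pss": (0.0, 40.0),
    "dars": (0.0, 68.0),
    "anticipation": None,  # filled from config.rating_scale
}


@dataclass
class Cohort:
    """In-memory cohort: tidy tables plus the generating configuration."""

    participants: pd.DataFrame
    detection_trials: pd.DataFrame
    choice_trials: pd.DataFrame
    mid_ratings: pd.DataFrame
    config: CohortConfig


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def _sample_truncated_mvn(n, means, sds, corr, bounds, rng, max_rounds=200):
    """Rejection-sample a multivariate normal row-wise into a box."""
    cov = np.outer(sds, sds) * corr
    out = np.empty((n, len(means)))
    need = np.arange(n)
    for _ in range(max_rounds):
        draw = rng.multivariate_normal(means, cov, size=len(need), method="cholesky")
        ok = np.ones(len(need), dtype=bool)
        for j, b in enumerate(bounds):
            if b is not None:
                ok &= (draw[:, j] >= b[0]) & (draw[:, j] <= b[1])
        out[need[ok]] = draw[ok]
        need = need[~ok]
        if need.size == 0:
            return out
    # give up on stragglers: clip the final draw into the box
    draw = rng.multivariate_normal(means, cov, size=len(need), method="cholesky")
    for j, b in enumerate(bounds):
        if b is not None:
            draw[:, j] = np.clip(draw[:, j], b[0], b[1])
    out[need] = draw
    return out


def generate_profiles(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n_participants`` latent profiles.

    Traits come from a truncated multivariate normal with the configured
    means, SDs and correlation matrix (male rows get additive mean shifts);
    latent capacity ``k_true`` is drawn independently of the traits; the
    diffusion starting point is shifted by
    ``capacity_bias_coupling * (k_true - k_mean)`` through a logistic link,
    so higher capacity biases choices toward the high-effort boundary.
    """
    config.validate()
    n = config.n_participants
    sexes = np.asarray(list(config.sex_proportions))
    probs = np.asarray([config.sex_proportions[s] for s in sexes], dtype=float)
    sex = rng.choice(sexes, size=n, p=probs / probs.sum())

    lo, hi = config.age_bounds
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), lo, hi).round(0)

    bounds = [
        _TRAIT_BOUNDS[t] if t != "anticipation" else tuple(config.rating_scale)
        for t in TRAITS
    ]
    sds = np.array([config.trait_sds[t] for t in TRAITS])
    corr = config.correlation_matrix()
    base = np.array([config.trait_means[t] for t in TRAITS])
    shift = np.array([config.trait_male_shifts[t] for t in TRAITS])
    traits = np.empty((n, len(TRAITS)))
    for label, mult in (("female", 0.0), ("male", 1.0), ("other", 0.5)):
        mask = sex == label
        if mask.any():
            traits[mask] = _sample_truncated_mvn(
                int(mask.sum()), base + mult * shift, sds, corr, bounds, rng
            )

    k_true = np.maximum(rng.normal(config.k_mean, config.k_sd, size=n), 0.0)

    gm, gs = config.ddm_group_means, config.ddm_group_sds
    v = rng.normal(gm["v"], gs["v"], size=n) + config.capacity_drift_coupling * (
        k_true - config.k_mean
    )
    v = np.clip(v, -4.9, 4.9)
    a = np.maximum(rng.normal(gm["a"], gs["a"], size=n), 0.15)
    w_logit = (
        special.logit(gm["w"])
        + rng.normal(0.0, gs["w"], size=n)
        + config.capacity_bias_coupling * (k_true - config.k_mean)
    )
    w = np.clip(special.expit(w_logit), 1e-4, 1 - 1e-4)
    t0 = np.maximum(rng.normal(gm["t0"], gs["t0"], size=n), 0.05)

    completed_survey = rng.random(n) >= config.p_incomplete_survey
    completed_mid = rng.random(n) >= config.p_incomplete_mid
    repeated_task = rng.random(n) < config.p_repeated_task

    return pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "sex": sex,
            "age": age,
            "bdi_prop": traits[:, 0],
            "pss": traits[:, 1],
            "dars": traits[:, 2],
            "anticipation": traits[:, 3],
            "k_true": k_true,
            "v_true": v,
            "a_true": a,
            "w_true": w,
            "t0_true": t0,
            "completed_survey": completed_survey,
            "completed_mid": completed_mid,
            "repeated_task": repeated_task,
        }
    )


# ---------------------------------------------------------------------------
# change detection
# ---------------------------------------------------------------------------

def simulate_detection_response(
    k_true: float,
    set_size: int,
    is_change,
    guess_rate: float,
    rng: np.random.Generator,
):
    """Capacity-mixture response model for one or more trials.

    With probability ``min(k, N) / N`` the probe is held in memory and the
    response is correct; otherwise the response is a guess of "change" with
    probability ``guess_rate``.  Accepts a scalar or array ``is_change``;
    returns ``(response_change, correct)`` of matching shape.
    """
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    is_change_arr = np.atleast_1d(np.asarray(is_change, dtype=bool))
    p_mem = min(max(k_true, 0.0), set_size) / set_size
    in_memory = rng.random(is_change_arr.shape) < p_mem
    guess_change = rng.random(is_change_arr.shape) < guess_rate
    response = np.where(in_memory, is_change_arr, guess_change)
    correct = response == is_change_arr
    if np.isscalar(is_change) or np.ndim(is_change) == 0:
        return bool(response[0]), bool(correct[0])
    return response, correct


def _detection_rt(n, rng):
    # response times for probe judgements; not analysed downstream
    return np.exp(rng.normal(np.log(0.8), 0.3, size=n))


def generate_calibration_phase(
    profile: pd.Series, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Practice block plus the full calibration phase for one participant.

    Practice trials (counts 4/4/2 at set sizes 2/4/6, half change within
    each size rounded as evenly as possible) are flagged ``phase="practice"``
    and never enter capacity estimation.  The calibration phase has exactly
    ``n_calibration_trials / len(set_sizes)`` trials per set size, half
    change / half no-change per size, in randomised order.
    """
    rows = []
    for phase, counts_by_size in (
        ("practice", config.practice_counts),
        (
            "calibration",
            {
                s: config.n_calibration_trials // len(config.calibration_set_sizes)
                for s in config.calibration_set_sizes
            },
        ),
    ):
        sizes, changes = [], []
        for set_size, count in counts_by_size.items():
            n_change = count // 2
            sizes.extend([set_size] * count)
            changes.extend([True] * n_change + [False] * (count - n_change))
        sizes = np.asarray(sizes)
        changes = np.asarray(changes, dtype=bool)
        order = rng.permutation(len(sizes))
        sizes, changes = sizes[order], changes[order]
        responses = np.empty(len(sizes), dtype=bool)
        corrects = np.empty(len(sizes), dtype=bool)
        for s in np.unique(sizes):
            mask = sizes == s
            resp, corr = simulate_detection_response(
                profile["k_true"], int(s), changes[mask], config.guess_rate, rng
            )
            responses[mask], corrects[mask] = resp, corr
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": profile["participant_id"],
                    "phase": phase,
                    "trial_index": np.arange(1, len(sizes) + 1),
                    "set_size": sizes,
                    "is_change": changes,
                    "response_change": responses,
                    "correct": corrects,
                    "rt": _detection_rt(len(sizes), rng),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_choice_phase(
    profile: pd.Series,
    offered_sizes: tuple[int, int],
    config: CohortConfig,
    rng: np.random.Generator,
    sim_method: str = "inverse_cdf",
) -> pd.DataFrame:
    """30 effort-choice trials for one participant.

    Choice and decision time come from the Wiener simulator at the
    participant's true parameters (upper boundary = HR); the chosen trial is
    then performed at the corresponding set size and rewarded 10 (HR) or 1
    (LR) points when correct, 0 otherwise.
    """
    lr_size, hr_size = offered_sizes
    if hr_size <= lr_size:
        raise ConfigError("hr_set_size must exceed lr_set_size")
    params = DDMParams(
        v=profile["v_true"], a=profile["a_true"], w=profile["w_true"], t0=profile["t0_true"]
    )
    n = config.n_choice_trials
    is_hr, latency = simulate_ddm(params, n, rng, method=sim_method)
    set_sizes = np.where(is_hr, hr_size, lr_size)
    responses = np.empty(n, dtype=bool)
    corrects = np.empty(n, dtype=bool)
    is_change = rng.random(n) < 0.5
    for s in np.unique(set_sizes):
        mask = set_sizes == s
        resp, corr = simulate_detection_response(
            profile["k_true"], int(s), is_change[mask], config.guess_rate, rng
        )
        responses[mask], corrects[mask] = resp, corr
    points = np.where(
        corrects,
        np.where(is_hr, config.reward_points["HR"], config.reward_points["LR"]),
        0,
    )
    return pd.DataFrame(
        {
            "participant_id": profile["participant_id"],
            "trial_index": np.arange(1, n + 1),
            "lr_set_size": lr_size,
            "hr_set_size": hr_size,
            "choice": np.where(is_hr, "HR", "LR"),
            "choice_latency": latency,
            "performed_set_size": set_sizes,
            "performed_correct": corrects,
            "points": points,
        }
    )


def generate_mid_phase(
    profile: pd.Series, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Pre-trial excitement ratings, centred on the participant's latent
    anticipation with bounded noise and clamped to the rating scale."""
    lo, hi = config.rating_scale
    ratings = profile["anticipation"] + rng.normal(
        0.0, config.rating_noise_sd, size=config.n_mid_trials
    )
    return pd.DataFrame(
        {
            "participant_id": profile["participant_id"],
            "trial_index": np.arange(1, config.n_mid_trials + 1),
            "rating": np.clip(ratings, lo, hi),
        }
    )


# ---------------------------------------------------------------------------
# whole-cohort orchestration
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Generate the full study dataset for one cohort.

    The offered (LR, HR) set sizes come from the task's own running capacity
    estimate at set size 4 (rates tracked to 2 decimals, as a task
    implementation would), while the analysis-grade batch estimates are left
    to :func:`cogeffort.capacity.k_table`.  In the vanishingly rare case of
    an undefined running estimate the participant is offered (2, 6).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    profiles = generate_profiles(config, rng)

    detection, choices, mid = [], [], []
    for _, profile in profiles.iterrows():
        det = generate_calibration_phase(profile, config, rng)
        try:
            k4 = running_k_estimate(det, set_size=4, round_digits=2)
            offered = calibration_criterion(k4)
        except CriterionUndefinedError:
            offered = (2, 6)
        choices.append(generate_choice_phase(profile, offered, config, rng))
        detection.append(det)
        mid.append(generate_mid_phase(profile, config, rng))

    return Cohort(
        participants=profiles,
        detection_trials=pd.concat(detection, ignore_index=True),
        choice_trials=pd.concat(choices, ignore_index=True),
        mid_ratings=pd.concat(mid, ignore_index=True),
        config=config,
    )


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_FILES = {
    "participants.csv": PARTICIPANT_COLUMNS,
    "detection_trials.csv": DETECTION_COLUMNS,
    "choice_trials.csv": CHOICE_COLUMNS,
    "mid_ratings.csv": MID_COLUMNS,
}


def write_cohort(cohort: Cohort, path: str | os.PathLike) -> None:
    """Write the cohort tables as CSV plus a JSON copy of the config.

    Floats are serialised at full precision so that a fixed seed yields
    byte-identical files.
    """
    os.makedirs(path, exist_ok=True)
    tables = {
        "participants.csv": cohort.participants,
        "detection_trials.csv": cohort.detection_trials,
        "choice_trials.csv": cohort.choice_trials,
        "mid_ratings.csv": cohort.mid_ratings,
    }
    for name, df in tables.items():
        df.to_csv(os.path.join(path, name), index=False, float_format="%.17g")
    cohort.config.to_json(os.path.join(path, "config.json"))


def _read_table(path, name, required):
    full = os.path.join(path, name)
    if not os.path.exists(full):
        raise ParseError(f"{full}: file missing")
    try:
        df = pd.read_csv(full)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{full}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{full}: missing required column(s) {missing} (line 1)")
    return df


def read_cohort(path: str | os.PathLike) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    tables = {name: _read_table(path, name, cols) for name, cols in _FILES.items()}
    config = CohortConfig.from_json(os.path.join(path, "config.json"))
    return Cohort(
        participants=tables["participants.csv"],
        detection_trials=tables["detection_trials.csv"],
        choice_trials=tables["choice_trials.csv"],
        mid_ratings=tables["mid_ratings.csv"],
        config=config,
    )
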