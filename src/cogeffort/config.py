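"""Cohort and run configuration.

``CohortConfig`` holds every design constant of the simulated study: the
8-trial incentive-rating phase, the 120-trial change-detection calibration
phase (30 trials per set size in {2, 4, 6, 8}, half change / half no-change),
the 30-trial binary effort-choice phase with 1-point low-reward (LR) and
10-point high-reward (HR) options, the trait distribution (BDI proportion,
PSS, DARS, mean reward anticipation) with its correlation structure, the
latent-capacity distribution, and the group-level diffusion parameters that
generate effort choices.

Capacity is coupled to choice only through the diffusion starting point
(a logistic link on ``w``), so the headline capacity -> effort-preference
effect is recoverable by construction while trait effects on choice are null.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError

#: canonical trait order used by the correlation matrix and samplers
TRAITS = ("bdi_prop", "pss", "dars", "anticipation")

#: diffusion parameter order used throughout
DDM_PARAM_NAMES = ("v", "a", "w", "t0")


def _default_trait_correlations() -> list[list[float]]:
    # bdi~pss strongly positive, both weakly negative with anticipation,
    # dars mildly positive with bdi/pss; magnitudes are design defaults.
    return [
        [1.00, 0.60, 0.30, -0.20],
        [0.60, 1.00, 0.30, -0.20],
        [0.30, 0.30, 1.00, -0.10],
        [-0.20, -0.20, -0.10, 1.00],
    ]


@dataclass
class CohortConfig:
    """Full generative description of one synthetic cohort.

    Trait means/SDs are keyed by :data:`TRAITS`; ``trait_male_shifts`` are
    additive offsets applied to male participants (females get the base
    means, "other" the midpoint), emulating the observed sex differences in
    depressive traits and chronic stress.
    """

    n_participants: int = 429
    sex_proportions: dict[str, float] = field(
        default_factory=lambda: {"female": 332 / 429, "male": 92 / 429, "other": 5 / 429}
    )
    n_mid_trials: int = 8
    n_calibration_trials: int = 120
    calibration_set_sizes: tuple[int, ...] = (2, 4, 6, 8)
    practice_counts: dict[int, int] = field(default_factory=lambda: {2: 4, 4: 4, 6: 2})
    n_choice_trials: int = 30
    reward_points: dict[str, int] = field(default_factory=lambda: {"LR": 1, "HR": 10})

    # trait marginals (female baseline) and male offsets
    trait_means: dict[str, float] = field(
        default_factory=lambda: {"bdi_prop": 0.27, "pss": 20.8, "dars": 36.0, "anticipation": 3.95}
    )
    trait_sds: dict[str, float] = field(
        default_factory=lambda: {"bdi_prop": 0.17, "pss": 6.1, "dars": 11.0, "anticipation": 1.8}
    )
    trait_male_shifts: dict[str, float] = field(
        default_factory=lambda: {"bdi_prop": -0.08, "pss": -3.1, "dars": 2.0, "anticipation": 0.35}
    )
    trait_correlations: list[list[float]] = field(default_factory=_default_trait_correlations)

    age_mean: float = 20.4
    age_sd: float = 2.3
    age_bounds: tuple[float, float] = (16.0, 42.0)

    # latent visual short-term memory capacity (items), independent of traits
    k_mean: float = 3.0
    k_sd: float = 1.0

    # group-level diffusion parameters; w is parameterised on the logit
    # scale (mean given as a fraction, SD in logit units)
    ddm_group_means: dict[str, float] = field(
        default_factory=lambda: {"v": 0.60, "a": 1.60, "w": 0.58, "t0": 0.35}
    )
    ddm_group_sds: dict[str, float] = field(
        default_factory=lambda: {"v": 0.45, "a": 0.35, "w": 0.50, "t0": 0.08}
    )
    #: logit-units shift of the starting point per item of latent capacity
    capacity_bias_coupling: float = 0.35
    #: optional capacity -> drift coupling, off by default
    capacity_drift_coupling: float = 0.0

    guess_rate: float = 0.5
    rating_scale: tuple[float, float] = (1.0, 7.0)
    rating_noise_sd: float = 1.0

    # completion / compliance rates emulating the recruitment funnel
    p_incomplete_survey: float = 0.074
    p_incomplete_mid: float = 0.012
    p_repeated_task: float = 0.019

    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        counts = {
            "n_participants": self.n_participants,
            "n_mid_trials": self.n_mid_trials,
            "n_calibration_trials": self.n_calibration_trials,
            "n_choice_trials": self.n_choice_trials,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if abs(sum(self.sex_proportions.values()) - 1.0) > 1e-9:
            raise ConfigError("sex_proportions must sum to 1")
        if any(p < 0 for p in self.sex_proportions.values()):
            raise ConfigError("sex_proportions must be non-negative")
        if self.reward_points["HR"] <= self.reward_points["LR"]:
            raise ConfigError("HR reward must exceed LR reward")
        for name, sd in self.trait_sds.items():
            if sd < 0:
                raise ConfigError(f"trait SD for {name} is negative")
        if self.k_sd < 0 or any(s < 0 for s in self.ddm_group_sds.values()):
            raise ConfigError("standard deviations must be non-negative")
        if not 0.0 <= self.guess_rate <= 1.0:
            raise ConfigError("guess_rate must be a probability")
        corr = np.asarray(self.trait_correlations, dtype=float)
        if corr.shape != (len(TRAITS), len(TRAITS)):
            raise ConfigError(f"trait_correlations must be {len(TRAITS)}x{len(TRAITS)}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigError("trait_correlations must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ConfigError("trait_correlations must have a unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigError("trait_correlations must be positive semi-definite")
        lo, hi = self.rating_scale
        if not lo < hi:
            raise ConfigError("rating_scale bounds must be increasing")
        if not (0 < self.ddm_group_means["w"] < 1):
            raise ConfigError("group starting-point mean must lie in (0, 1)")
        if self.ddm_group_means["a"] <= 0 or self.ddm_group_means["t0"] < 0:
            raise ConfigError("boundary separation must be > 0 and t0 >= 0")

    # ------------------------------------------------------------------
    def correlation_matrix(self) -> np.ndarray:
        return np.asarray(self.trait_correlations, dtype=float)

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        # JSON has no tuples / int keys; normalise for round-tripping
        text = json.dumps(payload, indent=2, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CohortConfig":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        payload["calibration_set_sizes"] = tuple(payload.get("calibration_set_sizes", (2, 4, 6, 8)))
        payload["rating_scale"] = tuple(payload.get("rating_scale", (1.0, 7.0)))
        payload["age_bounds"] = tuple(payload.get("age_bounds", (16.0, 42.0)))
        payload["practice_counts"] = {int(k): int(v) for k, v in payload.get("practice_counts", {2: 4, 4: 4, 6: 2}).items()}
        cfg = cls(**payload)
        cfg.validate()
        return cfg
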