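"""Whole-display visual short-term memory capacity (Cowan's K).

A change-detection trial shows an array of ``N`` coloured squares followed by
a single probe; the participant reports "change" or "no change".  With the
hit rate ``h`` (change trials answered "change") and the false-alarm rate
``f`` (no-change trials answered "change"), the whole-display capacity
estimate at set size ``N`` is

    k = N * (h - f) / (1 - f)

The raw value is preserved: ``k`` may be negative when ``h < f`` and is not
clamped, and ``f = 1`` yields an undefined (flagged) estimate rather than an
infinity, so the downstream calibration criterion fails loudly.  Rates are
raw proportions, with no smoothing.

The set-size calibration criterion keys on the estimate at set size 4:
``k <= 3`` offers a (2, 6) low/high-effort pair, ``k > 3`` offers (4, 8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import CriterionUndefinedError, InsufficientDataError

__all__ = [
    "DetectionCounts",
    "KEstimate",
    "detection_counts",
    "k_estimate",
    "running_k_estimate",
    "calibration_criterion",
    "k_table",
]


@dataclass(frozen=True)
class DetectionCounts:
    """Per-set-size confusion tallies from calibration trials."""

    set_size: int
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self):
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.set_size < 1:
            raise ValueError("set_size must be >= 1")

    @property
    def n_change(self) -> int:
        return self.hits + self.misses

    @property
    def n_no_change(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def hit_rate(self) -> float:
        if self.n_change == 0:
            raise InsufficientDataError("no change trials: hit rate undefined")
        return self.hits / self.n_change

    @property
    def false_alarm_rate(self) -> float:
        if self.n_no_change == 0:
            raise InsufficientDataError("no no-change trials: false-alarm rate undefined")
        return self.false_alarms / self.n_no_change


@dataclass(frozen=True)
class KEstimate:
    set_size: int
    k: float  # NaN when undefined
    undefined: bool = False

    @property
    def defined(self) -> bool:
        return not self.undefined


def detection_counts(trials: pd.DataFrame, set_size: int) -> DetectionCounts:
    """Tally hits/misses/false alarms/correct rejections at one set size.

    ``trials`` must carry boolean ``is_change`` and ``response_change``
    columns; only rows with ``phase == "calibration"`` (when a ``phase``
    column is present) and the requested ``set_size`` are counted.  Order
    of rows is irrelevant.
    """
    sub = trials
    if "phase" in sub.columns:
        sub = sub[sub["phase"] == "calibration"]
    sub = sub[sub["set_size"] == set_size]
    is_change = sub["is_change"].to_numpy(dtype=bool)
    said_change = sub["response_change"].to_numpy(dtype=bool)
    return DetectionCounts(
        set_size=set_size,
        hits=int(np.sum(is_change & said_change)),
        misses=int(np.sum(is_change & ~said_change)),
        false_alarms=int(np.sum(~is_change & said_change)),
        correct_rejections=int(np.sum(~is_change & ~said_change)),
    )


def k_estimate(counts: DetectionCounts) -> KEstimate:
    """Whole-display K from confusion tallies; see the module docstring."""
    if counts.n_change == 0 or counts.n_no_change == 0:
        raise InsufficientDataError(
            f"set size {counts.set_size}: need at least one change and one "
            "no-change trial"
        )
    h = counts.hit_rate
    f = counts.false_alarm_rate
    if f >= 1.0:
        return KEstimate(set_size=counts.set_size, k=float("nan"), undefined=True)
    k = counts.set_size * (h - f) / (1.0 - f)
    return KEstimate(set_size=counts.set_size, k=float(k))


def running_k_estimate(
    trials: pd.DataFrame,
    set_size: int,
    round_digits: int | None = None,
) -> KEstimate:
    """Trial-by-trial cumulative K at one set size, as the task computes it.

    After every trial of the given set size the hit and false-alarm rates are
    recomputed from the cumulative counts and K is re-evaluated; the value
    after the final trial is returned.  Intermediate states with an empty
    cell or ``f = 1`` are undefined and skipped.  ``round_digits`` optionally
    rounds the cumulative rates before each evaluation, emulating a task
    implementation that tracks rates at fixed precision; with rounding the
    final running estimate can differ slightly from the batch estimate on the
    same trials (without rounding they coincide, both using the full final
    tallies).
    """
    sub = trials
    if "phase" in sub.columns:
        sub = sub[sub["phase"] == "calibration"]
    sub = sub[sub["set_size"] == set_size]
    if len(sub) == 0:
        raise InsufficientDataError(f"no calibration trials at set size {set_size}")
    is_change = sub["is_change"].to_numpy(dtype=bool)
    said_change = sub["response_change"].to_numpy(dtype=bool)

    hits = fas = n_change = n_no = 0
    last: KEstimate | None = None
    for chg, resp in zip(is_change, said_change):
        if chg:
            n_change += 1
            hits += int(resp)
        else:
            n_no += 1
            fas += int(resp)
        if n_change == 0 or n_no == 0:
            continue
        h = hits / n_change
        f = fas / n_no
        if round_digits is not None:
            h = round(h, round_digits)
            f = round(f, round_digits)
        if f >= 1.0:
            last = KEstimate(set_size=set_size, k=float("nan"), undefined=True)
            continue
        last = KEstimate(set_size=set_size, k=float(set_size * (h - f) / (1.0 - f)))
    if last is None:
        return KEstimate(set_size=set_size, k=float("nan"), undefined=True)
    return last


def calibration_criterion(k_at_4: KEstimate | float) -> tuple[int, int]:
    """Map the set-size-4 capacity estimate to the offered (LR, HR) sizes.

    ``k <= 3`` -> (2, 6); ``k > 3`` -> (4, 8).  An undefined estimate raises
    :class:`CriterionUndefinedError`; the caller decides whether to exclude.
    """
    if isinstance(k_at_4, KEstimate):
        if k_at_4.undefined or not np.isfinite(k_at_4.k):
            raise CriterionUndefinedError("capacity estimate at set size 4 is undefined")
        k = k_at_4.k
    else:
        k = float(k_at_4)
        if not np.isfinite(k):
            raise CriterionUndefinedError("capacity estimate at set size 4 is undefined")
    return (2, 6) if k <= 3.0 else (4, 8)


def k_table(detection_trials: pd.DataFrame, set_sizes=(2, 4, 6, 8)) -> pd.DataFrame:
    """Batch K per participant and set size.

    Returns a tidy frame ``participant_id, set_size, k, undefined_flag``.
    """
    rows = []
    for pid, grp in detection_trials.groupby("participant_id", sort=True):
        for n in set_sizes:
            est = k_estimate(detection_counts(grp, n))
            rows.append(
                {
                    "participant_id": pid,
                    "set_size": n,
                    "k": est.k,
                    "undefined_flag": est.undefined,
                }
            )
    return pd.DataFrame(rows)
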