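#!/usr/bin/env python
"""Run the statistical battery over the cleaned cohort.

Sex-difference t-tests, trait/capacity correlations, the binomial logistic
and linear regressions of effort preference, both 2x2 within-between
ANOVAs, the two multilevel models and the lagged-performance follow-up;
everything is serialized to results/stats_report.json.
"""

import argparse
import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from cogeffort.capacity import k_table
from cogeffort.cohort import read_cohort
from cogeffort.stats import (
    anova_mixed_2x2,
    apply_exclusions,
    classify_all,
    correlation_matrix,
    fit_group_logistic,
    fit_multilevel,
    fit_proportion_linear,
    lagged_performance_regression,
    pairwise_t_tests,
    summarize_by_group,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cohort = read_cohort(os.path.join(args.out, "cohort"))
    kept, _ = apply_exclusions(cohort)
    assignments = classify_all(kept.choice_trials)
    k4 = k_table(kept.detection_trials, set_sizes=(4,))[["participant_id", "k"]]
    table = kept.participants.merge(k4, on="participant_id").merge(
        assignments, on="participant_id"
    )
    long = kept.choice_trials.merge(
        assignments[["participant_id", "group"]], on="participant_id"
    )
    trial_level = kept.choice_trials.merge(
        table[["participant_id", "sex", "k", "bdi_prop", "pss", "anticipation"]],
        on="participant_id",
    )

    report = {
        "sex_differences": {m: r.to_dict() for m, r in pairwise_t_tests(table).items()},
        "correlations": correlation_matrix(table).to_dict(orient="records"),
        "group_logistic": fit_group_logistic(table).to_dict(),
        "proportion_linear": fit_proportion_linear(table).to_dict(),
        "anova_accuracy": anova_mixed_2x2(long, "performed_correct").to_dict(),
        "anova_latency": anova_mixed_2x2(long, "choice_latency").to_dict(),
        "summary_by_group": summarize_by_group(kept.choice_trials, assignments).to_dict(
            orient="records"
        ),
        "multilevel_accuracy": fit_multilevel(trial_level, "performed_correct").to_dict(),
        "multilevel_latency": fit_multilevel(trial_level, "choice_latency").to_dict(),
        "lagged_performance": lagged_performance_regression(
            kept.choice_trials, assignments
        ).to_dict(),
    }
    path = os.path.join(args.out, "stats_report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)

    logit = report["group_logistic"]
    print(f"wrote {path}")
    print(
        "logistic regression (effort group): K estimate beta "
        f"{logit['coef']['k']:.3f} (e^b {logit['odds_ratios']['k']:.2f}, "
        f"p {logit['pvalues']['k']:.2g}); trait p-values "
        + ", ".join(f"{t} {logit['pvalues'][t]:.2f}" for t in ("bdi_prop", "pss", "anticipation"))
    )
    tt = report["anova_accuracy"]["effects"][1]
    print(
        f"accuracy ANOVA, trial-type effect: F(1,{tt['df2']}) = {tt['F']:.1f}, "
        f"ges = {tt['ges']:.3f}"
    )
    print(pd.DataFrame(report["summary_by_group"]).round(3).to_string(index=False))


if __name__ == "__main__":
    main()
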