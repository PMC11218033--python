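#!/usr/bin/env python
"""Estimate working-memory capacity and apply the exclusion rules.

Reads the simulated cohort, computes whole-display K per set size, applies
the compliance exclusions, classifies effort phenotypes (>70% HR choices =
high effort) and writes k_estimates.csv, exclusions.csv, assignments.csv.
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from cogeffort.capacity import k_table
from cogeffort.cohort import read_cohort
from cogeffort.stats import apply_exclusions, classify_all


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cohort = read_cohort(os.path.join(args.out, "cohort"))
    kept, log = apply_exclusions(cohort)
    ktab = k_table(kept.detection_trials)
    assignments = classify_all(kept.choice_trials)

    ktab.to_csv(os.path.join(args.out, "k_estimates.csv"), index=False)
    log.to_csv(os.path.join(args.out, "exclusions.csv"), index=False)
    assignments.to_csv(os.path.join(args.out, "assignments.csv"), index=False)

    print(f"kept {len(kept.participants)} of {len(cohort.participants)} participants")
    if len(log):
        print(log["reason"].value_counts().to_string())
    k4 = ktab.query("set_size == 4")["k"]
    print(f"K at set size 4: mean {k4.mean():.2f}, SD {k4.std():.2f}")
    print(f"high-effort group: {(assignments['group'] == 'high_effort').mean():.1%}")


if __name__ == "__main__":
    main()
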