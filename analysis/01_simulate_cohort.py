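#!/usr/bin/env python
"""Simulate the study cohort.

Generates n = 429 participants through all four task phases (incentive
ratings, practice, change-detection calibration, effort choice) and writes
the cohort tables under results/cohort/.
"""

import argparse
import dataclasses
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from cogeffort.cohort import generate_cohort, write_cohort
from cogeffort.config import CohortConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    ap.add_argument("--n-participants", type=int, default=429)
    args = ap.parse_args()

    cfg = dataclasses.replace(
        CohortConfig(), n_participants=args.n_participants, seed=args.seed
    )
    cohort = generate_cohort(cfg)
    out = os.path.join(args.out, "cohort")
    write_cohort(cohort, out)

    ch = cohort.choice_trials
    prop_hr = ch.groupby("participant_id")["choice"].apply(lambda s: (s == "HR").mean())
    print(f"wrote {len(cohort.participants)} participants to {out}/")
    print(f"  mean proportion of HR choices: {prop_hr.mean():.3f}")
    print(f"  choice-phase accuracy: HR {ch[ch.choice=='HR'].performed_correct.mean():.3f}, "
          f"LR {ch[ch.choice=='LR'].performed_correct.mean():.3f}")


if __name__ == "__main__":
    main()
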