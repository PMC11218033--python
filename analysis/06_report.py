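#!/usr/bin/env python
"""Render the human-readable markdown report for a completed run.

Collects every serialized result under the output directory into
results/report.md; sections whose stage did not run are marked explicitly.
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from cogeffort.pipeline import render_report


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    text = render_report(args.out)
    print(f"wrote {os.path.join(args.out, 'report.md')} ({len(text.splitlines())} lines)")


if __name__ == "__main__":
    main()
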