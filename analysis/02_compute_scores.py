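#!/usr/bin/env python
"""Compute the eight dementia risk scores (prorated, z, tertiles).

Scores every participant with each bundled index, prorating incomplete
profiles to the full theoretical scale, and writes per-participant scores
(full and demographics-stripped variants) plus Table-1-style descriptives.
"""

import argparse
from pathlib import Path

from cogrisk.cohort import read_cohort_csv
from cogrisk.pipeline import _analysis_scores, summarize_cohort
from cogrisk.scoring import load_bundled_definitions, strip_demographics


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort_csv(args.cohort)
    defs = load_bundled_definitions()
    scores = _analysis_scores(cohort, defs)
    stripped = {k: strip_demographics(d) for k, d in defs.items()}
    scores_stripped = _analysis_scores(cohort, stripped)
    scores.to_csv(args.out / "scores.csv", index=False, float_format="%.10g")
    scores_stripped.to_csv(args.out / "scores_stripped.csv", index=False,
                           float_format="%.10g")
    desc = summarize_cohort(cohort, scores)
    desc.to_csv(args.out / "descriptives.csv", index=False,
                float_format="%.10g")

    for key in defs:
        col = scores[f"{key}_prorated"]
        comp = scores[f"{key}_complete"].mean()
        print(f"{key:12s} mean {col.mean():7.2f}  SD {col.std():6.2f}  "
              f"range [{col.min():7.2f}, {col.max():7.2f}]  "
              f"complete {comp:.0%}")
    print(f"wrote {args.out / 'scores.csv'}")


if __name__ == "__main__":
    main()
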