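#!/usr/bin/env python
"""Mixed-effects models of MoCA level and annual change per risk score.

For each index: continuous (z) and tertile models with IPW, plus the
demographics-stripped continuous variant and age/sex moderation models.
The time x score interaction is the headline quantity: extra annual MoCA
change per 1 SD (or per tertile vs low).
"""

import argparse
from pathlib import Path

import pandas as pd

from cogrisk.cohort import read_cohort_csv
from cogrisk.ipw import attrition_weights_for_cohort
from cogrisk.longitudinal import build_long_table, fit_lmm, fit_lmm_moderation
from cogrisk.pipeline import _analysis_scores, _lmm_rows
from cogrisk.scoring import load_bundled_definitions, strip_demographics


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--no-ipw", action="store_true")
    args = ap.parse_args()

    cohort = read_cohort_csv(args.cohort)
    defs = load_bundled_definitions()
    scores = _analysis_scores(cohort, defs)
    stripped_defs = {k: strip_demographics(d) for k, d in defs.items()}
    scores_stripped = _analysis_scores(cohort, stripped_defs)
    if args.no_ipw:
        weights = pd.Series(1.0, index=cohort.index)
    else:
        weights, _, _ = attrition_weights_for_cohort(cohort)

    rows = []
    for key in defs:
        t = build_long_table(cohort, scores[f"{key}_z"], weights=weights)
        rows += _lmm_rows(fit_lmm(t), key, "continuous", "with_demographics")
        tt = build_long_table(cohort, scores[f"{key}_tertile"],
                              form="tertile", weights=weights)
        rows += _lmm_rows(fit_lmm(tt), key, "tertile", "with_demographics")
        ts = build_long_table(cohort, scores_stripped[f"{key}_z"],
                              weights=weights)
        rows += _lmm_rows(fit_lmm(ts), key, "continuous",
                          "without_demographics")
        tm = build_long_table(cohort, scores_stripped[f"{key}_z"],
                              weights=weights, moderators=True)
        rows += _lmm_rows(fit_lmm_moderation(tm), key, "continuous",
                          "moderation")
    frame = pd.DataFrame(rows)
    frame.to_csv(args.out / "lmm.csv", index=False, float_format="%.10g")

    show = frame[(frame["form"] == "continuous")
                 & (frame["model"] == "with_demographics")
                 & (frame["term"] == "time:score_z")]
    print("annual MoCA change per 1 SD of risk score (with demographics):")
    for _, r in show.iterrows():
        print(f"  {r['score']:12s} {r['estimate']:+.3f} "
              f"[{r['ci_low']:+.3f}, {r['ci_high']:+.3f}]")
    print(f"wrote {args.out / 'lmm.csv'}")


if __name__ == "__main__":
    main()
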