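#!/usr/bin/env python
"""Fit the follow-up participation model and build truncated IP weights.

Logistic model of attendance on age, education, heart disease, depression,
diabetes, hypertension and stroke; weights are inverse predicted
probabilities for attendees, truncated at the 99th percentile.
"""

import argparse
import json
from pathlib import Path

from cogrisk.cohort import read_cohort_csv
from cogrisk.ipw import attrition_weights_for_cohort


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = read_cohort_csv(args.cohort)
    weights, model, ipw = attrition_weights_for_cohort(cohort)
    ipw.frame().to_csv(args.out / "ipw.csv", index=False,
                       float_format="%.10g")
    (args.out / "participation_model.json").write_text(
        json.dumps(model.summary_dict(), indent=2, sort_keys=True) + "\n")

    print("participation model (log-odds):")
    for name, coef in model.params.items():
        print(f"  {name:14s} {coef:+.4f} (SE {model.bse[name]:.4f})")
    print(f"weight cap (99th pct): {ipw.cap_value:.3f}; "
          f"{ipw.n_truncated} weights truncated")
    print(f"mean truncated weight on attendees: "
          f"{ipw.truncated_weight.mean():.3f}")


if __name__ == "__main__":
    main()
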