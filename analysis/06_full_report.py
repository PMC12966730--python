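#!/usr/bin/env python
"""One-shot reproduction: full seeded pipeline with markdown report.

Equivalent to running scripts 01-05 in sequence through the pipeline
orchestrator; writes every stage output plus report.md under --out.
"""

import argparse
from pathlib import Path

from cogrisk.cohort import SimConfig
from cogrisk.pipeline import RunConfig, run_pipeline


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=7221)
    ap.add_argument("--out", type=Path, default=Path("results/full_run"))
    args = ap.parse_args()

    cfg = RunConfig(sim=SimConfig(n_participants=args.n, seed=args.seed),
                    out_dir=str(args.out))
    bundle = run_pipeline(cfg)
    print((args.out / "report.md").read_text())


if __name__ == "__main__":
    main()
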