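#!/usr/bin/env python
"""Monte-Carlo study of slope estimation under MAR/MNAR dropout mixes.

For each (cohort size, MNAR/MAR split) cell: calibrate the dropout
mechanisms to the target proportions, simulate replicate cohorts with a
28-day follow-up and true slope 0.39 log(mm^3)/week, fit the
random-intercept-and-slope linear mixed model and the joint
shared-random-effects model, and summarize mean estimate, bias %, 95%-CI
coverage % and convergence % per model.

The headline pattern: the mixed model is unbiased with nominal coverage
whenever dropout is driven by the observed volumes (MAR sacrifices),
whatever the split; the joint model is unbiased when deaths follow its own
latent hazard (pure MNAR) and converges less often as MAR contamination
grows.

Usage:
    python analysis/03_simulation_study.py --sizes 300,100
        --splits 50:0,0:50 --reps 100 --seed 20230126 --out results/table1.csv
"""

import argparse
import time

from mctmodels import run_grid


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sizes", type=str, default="300,100")
    ap.add_argument("--splits", type=str, default="50:0,0:50",
                    help="MNAR:MAR percentage pairs, comma-separated")
    ap.add_argument("--reps", type=int, default=100)
    ap.add_argument("--seed", type=int, default=20230126)
    ap.add_argument("--models", type=str, default="lmm,joint")
    ap.add_argument("--out", type=str, default="results/table1.csv")
    args = ap.parse_args()

    sizes = tuple(int(s) for s in args.sizes.split(","))
    splits = tuple((float(a) / 100, float(b) / 100)
                   for a, b in (s.split(":") for s in args.splits.split(",")))
    models = tuple(args.models.split(","))

    t0 = time.time()
    table = run_grid(sizes=sizes, splits=splits, n_reps=args.reps,
                     base_seed=args.seed, models=models)
    table.to_csv(args.out, index=False)
    cols = ["n_mice", "split", "model", "mean_estimate", "bias_pct",
            "coverage_pct", "convergence_pct", "n_reps"]
    print(table[cols].round(3).to_string(index=False))
    print(f"\nwrote {args.out} ({time.time() - t0:.0f}s)")


if __name__ == "__main__":
    main()
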