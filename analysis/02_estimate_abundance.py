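#!/usr/bin/env python
"""Chapman/Petersen abundance estimates and dead-pup mortality summaries.

Reads the simulated recapture sessions from results/run/, writes
abundance_estimates.csv and mortality.csv there, and reports how often
the 95% CIs bracket the simulator's true abundance.
"""

import argparse

import pandas as pd

from pupmonitor import pipeline as pl
from pupmonitor import synthetic_data as sd

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", default="results/run")
args = parser.parse_args()

cfg = pl.RunConfig(
    outdir=args.outdir, sim_config=sd.default_config(args.seed), stages=("estimate",)
)
manifest = pl.run_pipeline(cfg)
assert manifest["stages"]["estimate"]["status"] == "complete", manifest

est = pd.read_csv(f"{args.outdir}/abundance_estimates.csv")
truth = pd.read_csv(f"{args.outdir}/ground_truth.csv")
merged = est.merge(truth[["colony", "year", "true_n"]], on=["colony", "year"])
hit = (merged["ci_lower"] <= merged["true_n"]) & (merged["true_n"] <= merged["ci_upper"])
print(f"estimated {len(est)} colony-years; "
      f"95% CI covers true N in {100 * hit.mean():.1f}% of them")

mort = pd.read_csv(f"{args.outdir}/mortality.csv")
for colony, grp in mort.groupby("colony"):
    print(f"  {colony}: mean dead fraction {grp['dead_fraction_pct'].mean():.1f}% "
          f"(range {grp['dead_fraction_pct'].min():.1f}-"
          f"{grp['dead_fraction_pct'].max():.1f}%)")
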