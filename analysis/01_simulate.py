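#!/usr/bin/env python
"""Generate the synthetic multi-cohort home-care dataset.

Six cohorts with a planted cross-cohort event-rate spread (roughly 27-41%
before covariate load), 123 binary assessment items with 16 planted risk
items (true OR 1.5-2.0), two protective items (0.60/0.65), a strong prior
hospital/ED-use effect (OR 4), and everything else null.  Writes
results/cohort.csv for the downstream stages.

Run:  python analysis/01_simulate.py [--n 60000] [--seed 0]
"""

import argparse
from pathlib import Path

import edrisk

ap = argparse.ArgumentParser()
ap.add_argument("--n", type=int, default=60_000)
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out-dir", type=Path, default=Path("results"))
args = ap.parse_args()

cfg = edrisk.default_config(n_persons=args.n, seed=args.seed)
ds = edrisk.generate_cohort(cfg)
args.out_dir.mkdir(parents=True, exist_ok=True)
edrisk.write_cohort_csv(ds, args.out_dir / "cohort.csv")

rates = ds.groupby("cohort")["outcome"].mean()
print(f"wrote {len(ds)} records, {len(cfg.catalog)} items -> {args.out_dir/'cohort.csv'}")
print("follow-up hospital/ED rate by cohort:")
for label, r in rates.items():
    print(f"  {label}: {100 * r:.1f}%")
print(f"overall: {100 * ds['outcome'].mean():.1f}%; "
      f"prior-use prevalence: {100 * ds['prior_use'].mean():.1f}%")
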