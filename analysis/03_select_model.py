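#!/usr/bin/env python
"""Staged stepwise logistic selection and index definition.

Stage 1 runs forward selection (likelihood-ratio entry at 0.05) over the
screened clinical-complication / disease / treatment candidates; stage 2
adds the remaining six domains.  After every entry, covariates whose
adjusted OR drops below 1.2 (or above 1/1.2 for protective items) in the
derivation model or its validation refit are pruned.  Writes
results/model.json (with the full selection trace) and
results/index_definition.json.

Run after 02_screen.py:  python analysis/03_select_model.py [--seed 0]
"""

import argparse
import json
from pathlib import Path

import edrisk
from edrisk.index import build_index_definition
from edrisk.screening import screen_all
from edrisk.selection import stepwise_select, validation_refit

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--out-dir", type=Path, default=Path("results"))
args = ap.parse_args()

catalog = edrisk.default_catalog()
ds = edrisk.read_cohort_csv(args.out_dir / "cohort.csv")
ds = edrisk.split_derivation_validation(ds, 2 / 3, seed=args.seed)
screening = screen_all(ds, catalog)

deriv = ds[ds["split"] == "derivation"]
valid = ds[ds["split"] == "validation"]
model = stepwise_select(deriv, valid, screening, catalog)
vmodel = validation_refit(model, valid)

payload = model.to_dict()
payload["odds_ratios_validation"] = vmodel.odds_ratios()
with open(args.out_dir / "model.json", "w", encoding="utf-8") as fh:
    json.dump(payload, fh, indent=2, sort_keys=True)
    fh.write("\n")

definition = build_index_definition(model)
definition.to_json(args.out_dir / "index_definition.json")

planted = set(catalog.risk_items())
sel = set(model.covariates)
print(f"final model: {len(model.covariates)} covariates "
      f"({len(sel & planted)}/{len(planted)} planted risk items recovered, "
      f"{len(sel & set(catalog.protective_items()))} protective, "
      f"{len(sel - planted - set(catalog.protective_items()))} null)")
print("adjusted ORs (derivation / validation):")
for item in model.covariates:
    print(f"  {item}: {model.odds_ratios()[item]:.2f} / "
          f"{vmodel.odds_ratios()[item]:.2f}")
drops = [e for e in model.selection_trace if e["event"] == "drop"]
print(f"{len(drops)} candidates entered but failed the dual-sample OR>=1.2 retention rule")
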