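"""The count-based hospital/ED risk index.

The index is an unweighted count of a person's present risk factors
(default 16 items), minus one point when one or both protective factors
(a dementia diagnosis, day-care participation) are present, floored at
zero and reported on a 0-6 scale where 6 means "six or more".  The
extended 0-12 variant additionally encodes baseline prior hospital/ED
use: categories 0-6 are the no-prior-use scale and 7-12 the prior-use
scale (prior-use scores of five or more share the top cell).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .logistic import LogisticModel

#: canonical 16 risk items: 14 named final-model items plus two slots
#: (polypharmacy and heart failure) — see docs for the slot rationale
DEFAULT_RISK_ITEMS = [
    "pneumonia",
    "urinary_tract_infection",
    "stasis_ulcer",
    "wound_care",
    "unintended_weight_loss",
    "status_decline_90d",
    "unscheduled_md_visits",
    "falls",
    "renal_failure",
    "emphysema",
    "cancer",
    "daily_nurse_monitoring",
    "iv_infusion",
    "injection_medication",
    "nine_plus_medications",
    "congestive_heart_failure",
]

DEFAULT_PROTECTIVE_ITEMS = ["alzheimers", "day_care"]


@dataclass
class RiskIndexDefinition:
    """The scoring rule: which items count, which subtract, how to cap."""

    risk_items: list[str] = field(default_factory=lambda: list(DEFAULT_RISK_ITEMS))
    protective_items: list[str] = field(default_factory=lambda: list(DEFAULT_PROTECTIVE_ITEMS))
    cap: int = 6
    prior_use_extension: bool = True

    def __post_init__(self) -> None:
        if set(self.risk_items) & set(self.protective_items):
            raise ConfigurationError("risk and protective items must be disjoint")
        if len(set(self.risk_items)) != len(self.risk_items):
            raise ConfigurationError("duplicate risk items")
        if self.cap < 1:
            raise ConfigurationError("cap must be >= 1")
        if not self.risk_items:
            raise ConfigurationError("index requires at least one risk item")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "risk_items": self.risk_items,
                    "protective_items": self.protective_items,
                    "cap": self.cap,
                    "prior_use_extension": self.prior_use_extension,
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RiskIndexDefinition":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        unknown = set(raw) - {"risk_items", "protective_items", "cap", "prior_use_extension"}
        if unknown:
            raise ConfigurationError(f"unknown index definition keys: {sorted(unknown)}")
        return cls(
            risk_items=list(raw["risk_items"]),
            protective_items=list(raw.get("protective_items", [])),
            cap=int(raw.get("cap", 6)),
            prior_use_extension=bool(raw.get("prior_use_extension", True)),
        )


def default_index_definition() -> RiskIndexDefinition:
    return RiskIndexDefinition()


@dataclass(frozen=True)
class RiskScore:
    raw_count: int
    adjusted: int
    category: int
    extended_category: int | None = None


def build_index_definition(model: LogisticModel,
                           prior_use_extension: bool = True,
                           cap: int = 6) -> RiskIndexDefinition:
    """Turn a fitted final model into a scoring rule.

    Covariates with OR > 1 become risk items, OR < 1 protective items;
    an OR of exactly 1 has no defensible role and is rejected.
    """
    ors = model.odds_ratios()
    if not ors:
        raise ConfigurationError("cannot build an index from an intercept-only model")
    risk, protective = [], []
    for item, v in ors.items():
        if v > 1.0:
            risk.append(item)
        elif v < 1.0:
            protective.append(item)
        else:
            raise ConfigurationError(f"covariate {item!r} has OR exactly 1 (ambiguous role)")
    if not risk:
        raise ConfigurationError("final model contains no risk covariates")
    return RiskIndexDefinition(risk_items=risk, protective_items=protective,
                               cap=cap, prior_use_extension=prior_use_extension)


def score(record, definition: RiskIndexDefinition) -> RiskScore:
    """Score one person (a mapping / Series of item values plus prior_use).

    No imputation: a missing item value is an error.
    """
    for i in list(definition.risk_items) + list(definition.protective_items):
        try:
            v = record[i]
        except (KeyError, IndexError) as exc:
            raise DataError(f"record lacks item required by the index: {i!r}") from exc
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise DataError(f"missing value for item {i!r}")
    raw = sum(int(record[i]) for i in definition.risk_items)
    protected = any(int(record[i]) == 1 for i in definition.protective_items)
    adjusted = max(0, raw - 1) if protected else raw
    category = min(adjusted, definition.cap)
    extended = None
    if definition.prior_use_extension:
        try:
            prior = int(record["prior_use"])
        except (KeyError, IndexError) as exc:
            raise DataError("record lacks prior_use flag") from exc
        extended = category if prior == 0 else 7 + min(adjusted, 5)
    return RiskScore(raw_count=int(raw), adjusted=int(adjusted),
                     category=int(category), extended_category=extended)


def score_dataset(dataset: pd.DataFrame,
                  definition: RiskIndexDefinition) -> pd.DataFrame:
    """Vectorised scores for every record, order-preserving.

    Returns a DataFrame with person_id, raw_count, adjusted, category and
    (if enabled) extended_category.
    """
    missing = [i for i in definition.risk_items + definition.protective_items
               if i not in dataset.columns]
    if missing:
        raise DataError(f"dataset lacks index items: {missing}")
    R = dataset[definition.risk_items].to_numpy(dtype=np.float64)
    if np.isnan(R).any():
        raise DataError("missing risk-item values")
    raw = R.sum(axis=1).astype(np.int64)
    if definition.protective_items:
        P = dataset[definition.protective_items].to_numpy(dtype=np.float64)
        if np.isnan(P).any():
            raise DataError("missing protective-item values")
        protected = (P == 1).any(axis=1)
    else:
        protected = np.zeros(len(dataset), dtype=bool)
    adjusted = np.where(protected, np.maximum(0, raw - 1), raw)
    category = np.minimum(adjusted, definition.cap)
    out = pd.DataFrame({
        "person_id": dataset["person_id"].to_numpy() if "person_id" in dataset.columns
        else np.arange(len(dataset)),
        "raw_count": raw,
        "adjusted": adjusted,
        "category": category,
    })
    if definition.prior_use_extension:
        if "prior_use" not in dataset.columns:
            raise DataError("dataset lacks prior_use column")
        prior = dataset["prior_use"].to_numpy(dtype=np.int64)
        out["extended_category"] = np.where(prior == 0, category,
                                            7 + np.minimum(adjusted, 5))
    return out


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False, lineterminator="\n")
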