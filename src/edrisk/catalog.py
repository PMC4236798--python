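"""Analytic item catalog: 123 dichotomous assessment items in nine domains.

The catalog is the single source of truth for the synthetic generator and
for the screening/selection stages: each item carries its domain, its
planted log-odds effect on the follow-up hospital/ED outcome
(``true_beta``, zero for null items), and its population prevalence.

The default profile mirrors the analytic inventory of a comprehensive
home-care assessment: 28 clinical complications, 19 disease diagnoses,
15 specialized treatments, 6 cognition/communication, 12 mood/behavior,
4 social supports, 11 function, 10 environment, 18 services (123 total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError

DOMAINS = (
    "clinical_complication",
    "disease",
    "treatment",
    "cognition_communication",
    "mood_behavior",
    "social_supports",
    "function",
    "environment",
    "services",
)

#: domain -> number of analytic items in the default profile
DEFAULT_DOMAIN_COUNTS = {
    "clinical_complication": 28,
    "disease": 19,
    "treatment": 15,
    "cognition_communication": 6,
    "mood_behavior": 12,
    "social_supports": 4,
    "function": 11,
    "environment": 10,
    "services": 18,
}


@dataclass(frozen=True)
class Item:
    """One dichotomous assessment item."""

    item_id: str
    domain: str
    true_beta: float = 0.0
    prevalence: float = 0.1

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ConfigurationError(f"unknown domain {self.domain!r} for {self.item_id}")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError(
                f"prevalence of {self.item_id} must lie in (0, 1), got {self.prevalence}"
            )
        if not math.isfinite(self.true_beta):
            raise ConfigurationError(f"non-finite true_beta for {self.item_id}")

    @property
    def true_or(self) -> float:
        return math.exp(self.true_beta)


@dataclass
class ItemCatalog:
    """Ordered collection of items with unique ids."""

    items: list[Item] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate item ids: {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def get(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def domain_of(self, item_id: str) -> str:
        return self.get(item_id).domain

    def domain_counts(self) -> dict[str, int]:
        counts = {d: 0 for d in DOMAINS}
        for it in self.items:
            counts[it.domain] += 1
        return counts

    def risk_items(self) -> list[str]:
        return [it.item_id for it in self.items if it.true_beta > 0]

    def protective_items(self) -> list[str]:
        return [it.item_id for it in self.items if it.true_beta < 0]

    def null_items(self) -> list[str]:
        return [it.item_id for it in self.items if it.true_beta == 0]


# ---------------------------------------------------------------------------
# Default planted truth
# ---------------------------------------------------------------------------

# The 16 planted elevated-risk items: (id, domain, true OR, prevalence).
# Rare complex treatments carry the larger effects, common items the
# smaller ones, so each planted marginal OR clears the 1.30 screen with
# comparable headroom at derivation-sample sizes.
_RISK_PROFILE = [
    ("pneumonia", "clinical_complication", 1.9, 0.04),
    ("urinary_tract_infection", "clinical_complication", 1.6, 0.12),
    ("stasis_ulcer", "clinical_complication", 1.9, 0.05),
    ("unintended_weight_loss", "clinical_complication", 1.6, 0.12),
    ("status_decline_90d", "clinical_complication", 1.5, 0.15),
    ("falls", "clinical_complication", 1.5, 0.30),
    ("unscheduled_md_visits", "clinical_complication", 1.5, 0.25),
    ("renal_failure", "disease", 1.8, 0.05),
    ("emphysema", "disease", 1.7, 0.08),
    ("cancer", "disease", 1.6, 0.10),
    ("congestive_heart_failure", "disease", 1.5, 0.15),
    ("wound_care", "treatment", 1.6, 0.15),
    ("daily_nurse_monitoring", "treatment", 1.7, 0.10),
    ("iv_infusion", "treatment", 2.0, 0.02),
    ("injection_medication", "treatment", 1.7, 0.08),
    ("nine_plus_medications", "treatment", 1.5, 0.35),
]

# The two planted protective items (presence lowers outcome odds).
_PROTECTIVE_PROFILE = [
    ("alzheimers", "disease", 0.60, 0.12),
    ("day_care", "services", 0.65, 0.10),
]

# Named null items with face validity; remaining slots are generic.
_NAMED_NULLS = {
    "clinical_complication": [
        "fever", "chest_pain", "diarrhea", "vomiting", "dizziness",
        "edema", "shortness_of_breath", "poor_self_rated_health",
        "pain", "unsteady_gait", "swallowing_problem", "delusions",
        "hallucinations", "bladder_incontinence", "bowel_incontinence",
    ],
    "disease": [
        "hypertension", "diabetes", "arthritis", "parkinsons",
        "osteoporosis", "cataract", "glaucoma", "thyroid_disease",
        "peripheral_vascular_disease", "hip_fracture", "head_trauma",
        "hemiplegia", "stroke", "coronary_artery_disease",
    ],
    "treatment": [
        "oxygen_therapy", "dialysis", "radiation", "blood_transfusion",
        "chemotherapy", "ostomy_care", "catheter_care", "tube_feeding",
        "physical_therapy", "occupational_therapy",
    ],
    "services": [
        "home_health_aide", "meals_on_wheels", "homemaking",
        "visiting_nurse", "respite_care", "transportation",
        "social_work", "alcohol_drug_treatment",
    ],
}

# Deterministic prevalence cycle for filler items (kept off round values).
_FILL_PREV = (0.05, 0.12, 0.22, 0.08, 0.31, 0.17, 0.26, 0.11, 0.38, 0.14)


def default_catalog(
    risk_or: float | None = None,
    protective_or: float | None = None,
    prior_scale: float = 1.0,
) -> ItemCatalog:
    """Build the default 123-item catalog with planted truth.

    Parameters
    ----------
    risk_or
        If given, override every planted risk item's odds ratio with this
        single value (used for the prior-use-dominant regime where
        per-item effects are modest, e.g. 1.2).
    protective_or
        If given, override both protective odds ratios.
    prior_scale
        Multiplier on every planted |beta| (0 gives an all-null catalog).
    """
    items: list[Item] = []
    for item_id, domain, or_, prev in _RISK_PROFILE:
        beta = math.log(risk_or if risk_or is not None else or_) * prior_scale
        items.append(Item(item_id, domain, beta, prev))
    for item_id, domain, or_, prev in _PROTECTIVE_PROFILE:
        beta = math.log(protective_or if protective_or is not None else or_) * prior_scale
        items.append(Item(item_id, domain, beta, prev))

    used = {it.domain: 0 for it in items}
    for it in items:
        used[it.domain] = used.get(it.domain, 0) + 1
    counts = {d: 0 for d in DOMAINS}
    for it in items:
        counts[it.domain] += 1

    k = 0
    for domain in DOMAINS:
        target = DEFAULT_DOMAIN_COUNTS[domain]
        named = list(_NAMED_NULLS.get(domain, []))
        idx = 1
        while counts[domain] < target:
            if named:
                item_id = named.pop(0)
            else:
                item_id = f"{domain}_{idx:02d}"
                idx += 1
            items.append(Item(item_id, domain, 0.0, _FILL_PREV[k % len(_FILL_PREV)]))
            k += 1
            counts[domain] += 1

    cat = ItemCatalog(items)
    assert len(cat) == sum(DEFAULT_DOMAIN_COUNTS.values())
    return cat


def all_null_catalog() -> ItemCatalog:
    """Default item inventory with every planted effect removed."""
    return default_catalog(prior_scale=0.0)


#: The five directional-consistency probe items used before pooling
#: cross-cohort data: two infections, heart failure, polypharmacy, and
#: the protective dementia diagnosis.
DEFAULT_PROBE_ITEMS = (
    "pneumonia",
    "congestive_heart_failure",
    "urinary_tract_infection",
    "alzheimers",
    "nine_plus_medications",
)
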