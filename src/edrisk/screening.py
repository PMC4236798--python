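"""Univariate odds-ratio screening of dichotomous items.

Each item is cross-tabulated against the follow-up hospital/ED outcome
separately in the derivation and validation samples.  An item is kept as a
risk factor when its OR meets or exceeds 1.30 in *both* samples, and as a
protective factor when its OR is 0.75 or lower in both; everything else is
neutral.  A directional poolability check over a small probe set decides
whether cohorts may be pooled at all.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import DEFAULT_PROBE_ITEMS, ItemCatalog
from .errors import ConfigurationError, DataError, UndefinedOddsRatioError
from .simulate import SPLIT_DERIVATION, SPLIT_VALIDATION, item_columns

RISK = "risk"
PROTECTIVE = "protective"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure-by-outcome counts: a=(1,1), b=(1,0), c=(0,1), d=(0,0)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("2x2 cell counts must be non-negative")
        if self.total == 0:
            raise DataError("2x2 table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ScreeningConfig:
    risk_threshold: float = 1.30
    protective_threshold: float = 0.75
    require_validation_confirmation: bool = True
    continuity_correction: float = 0.5  # added to all cells iff any cell is zero

    def __post_init__(self) -> None:
        if not (self.protective_threshold < 1.0 < self.risk_threshold):
            raise ConfigurationError(
                "thresholds must satisfy protective < 1 < risk, got "
                f"{self.protective_threshold} / {self.risk_threshold}"
            )
        if self.continuity_correction < 0:
            raise ConfigurationError("continuity_correction must be non-negative")


def build_table(dataset: pd.DataFrame, item_id: str, split_label: str) -> TwoByTwoTable:
    """Exact exposure-by-outcome cross-tabulation within one split."""
    if item_id not in dataset.columns:
        raise DataError(f"unknown item {item_id!r}")
    sub = dataset[dataset["split"] == split_label]
    if len(sub) == 0:
        raise DataError(f"split {split_label!r} is empty")
    x = sub[item_id].to_numpy()
    y = sub["outcome"].to_numpy()
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return TwoByTwoTable(a, b, c, d)


def odds_ratio(table: TwoByTwoTable, config: ScreeningConfig | None = None) -> float:
    """Cross-product odds ratio (a*d)/(b*c), continuity-corrected on zero cells.

    The Haldane–Anscombe correction adds ``continuity_correction`` to all
    four cells, but only when at least one cell is zero.
    """
    cfg = config or ScreeningConfig()
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if min(a, b, c, d) == 0.0:
        if max(a, b, c, d) == 0.0:
            raise UndefinedOddsRatioError("all four cells are zero")
        k = cfg.continuity_correction
        a, b, c, d = a + k, b + k, c + k, d + k
    if b * c == 0.0:
        raise UndefinedOddsRatioError("zero denominator after continuity correction")
    return (a * d) / (b * c)


def classify_item(or_derivation: float, or_validation: float,
                  config: ScreeningConfig | None = None) -> str:
    """Risk/protective/neutral under the dual-sample threshold rule."""
    cfg = config or ScreeningConfig()
    ors = [or_derivation] if not cfg.require_validation_confirmation \
        else [or_derivation, or_validation]
    for v in ors:
        if not (math.isfinite(v) and v > 0):
            raise DataError(f"odds ratio must be positive and finite, got {v}")
    if all(v >= cfg.risk_threshold for v in ors):
        return RISK
    if all(v <= cfg.protective_threshold for v in ors):
        return PROTECTIVE
    return NEUTRAL


@dataclass
class ScreeningResult:
    """Per-item derivation/validation ORs and classification."""

    table: pd.DataFrame  # columns: item_id, domain, or_derivation, or_validation, classification

    def items_with(self, classification: str) -> list[str]:
        sel = self.table[self.table["classification"] == classification]
        return sel["item_id"].tolist()

    @property
    def candidates(self) -> pd.DataFrame:
        """Non-neutral items (the stepwise candidate pool)."""
        return self.table[self.table["classification"] != NEUTRAL].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f",
                          lineterminator="\n")

    def to_json(self, path) -> None:
        records = self.table.to_dict(orient="records")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _split_or_vectors(dataset: pd.DataFrame, items: list[str], split_label: str,
                      cfg: ScreeningConfig) -> np.ndarray:
    """Vectorised per-item ORs within one split (NaN where undefined)."""
    sub = dataset[dataset["split"] == split_label]
    if len(sub) == 0:
        raise DataError(f"split {split_label!r} is empty")
    X = sub[items].to_numpy(dtype=np.float64)
    y = sub["outcome"].to_numpy(dtype=np.float64)
    a = y @ X
    exposed = X.sum(axis=0)
    events = y.sum()
    b = exposed - a
    c = events - a
    d = len(sub) - exposed - c
    cells = np.stack([a, b, c, d])
    any_zero = (cells == 0).any(axis=0)
    cells = cells + np.where(any_zero, cfg.continuity_correction, 0.0)[None, :]
    a, b, c, d = cells
    with np.errstate(divide="ignore", invalid="ignore"):
        ors = (a * d) / (b * c)
    ors[(b * c) == 0] = np.nan
    return ors


def screen_all(dataset: pd.DataFrame, catalog: ItemCatalog,
               config: ScreeningConfig | None = None) -> ScreeningResult:
    """Screen every catalog item on the derivation and validation samples.

    Per-item failures (undefined OR) are recorded as neutral with NaN ORs,
    not raised.
    """
    cfg = config or ScreeningConfig()
    items = catalog.item_ids
    missing = [i for i in items if i not in dataset.columns]
    if missing:
        raise DataError(f"dataset lacks catalog items: {missing[:5]}")
    or_d = _split_or_vectors(dataset, items, SPLIT_DERIVATION, cfg)
    or_v = _split_or_vectors(dataset, items, SPLIT_VALIDATION, cfg)
    cls = []
    for od, ov in zip(or_d, or_v):
        if not (np.isfinite(od) and od > 0) or (
            cfg.require_validation_confirmation and not (np.isfinite(ov) and ov > 0)
        ):
            cls.append(NEUTRAL)
        else:
            cls.append(classify_item(float(od), float(ov), cfg))
    table = pd.DataFrame(
        {
            "item_id": items,
            "domain": [catalog.domain_of(i) for i in items],
            "or_derivation": or_d,
            "or_validation": or_v,
            "classification": cls,
        }
    )
    return ScreeningResult(table)


def poolability_check(
    datasets_by_cohort: dict[str, pd.DataFrame],
    probe_items: tuple[str, ...] = DEFAULT_PROBE_ITEMS,
    config: ScreeningConfig | None = None,
) -> tuple[pd.DataFrame, bool]:
    """Directional-consistency check across cohorts before pooling.

    For each probe item, computes the whole-cohort OR in every cohort;
    the verdict is true iff each probe's ORs all lie on the same side of
    1.0 in every cohort.  A single cohort is vacuously consistent.
    """
    cfg = config or ScreeningConfig()
    if not datasets_by_cohort:
        raise DataError("at least one cohort is required")
    rows = []
    for label, ds in datasets_by_cohort.items():
        for item in probe_items:
            if item not in ds.columns:
                raise DataError(f"probe item {item!r} missing in cohort {label!r}")
            whole = ds.copy()
            whole["split"] = "all"
            tab = build_table(whole, item, "all")
            rows.append({"cohort": label, "item_id": item,
                         "odds_ratio": odds_ratio(tab, cfg)})
    table = pd.DataFrame(rows)
    verdict = True
    for item in probe_items:
        ors = table.loc[table["item_id"] == item, "odds_ratio"]
        if not ((ors > 1.0).all() or (ors < 1.0).all()):
            verdict = False
    return table, verdict


def dichotomize(dataset: pd.DataFrame, rules: dict[str, tuple[str, float]]) -> pd.DataFrame:
    """Rule-table hook for real (ordinal) data: item := 1{source >= cutoff}.

    ``rules`` maps new item_id -> (source column, cutoff).  The generator
    already emits binary items, so this is only needed for external data.
    """
    out = dataset.copy()
    for item_id, (source, cutoff) in rules.items():
        if source not in out.columns:
            raise DataError(f"dichotomization source column {source!r} missing")
        out[item_id] = (out[source] >= cutoff).astype(np.int8)
    return out
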