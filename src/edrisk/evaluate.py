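"""Stratified follow-up event-rate reporting for scored cohorts.

Computes exact outcome proportions across index categories, cohorts,
prior-use groups and item-defined disease subgroups, plus the two
qualitative checks the index is expected to satisfy: a non-decreasing
rate gradient over categories 0-6, and (when prior use is a strong
driver) the crossing where prior-use/zero-risk persons out-use
no-prior/six-plus persons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

#: stratifiers with a natural order for monotonicity reporting
ORDERED_STRATIFIERS = {"category", "extended_category", "raw_count", "adjusted"}


@dataclass
class StratifiedRates:
    """Per-stratum n, event count and rate; NaN rate flags an empty stratum."""

    stratifiers: list[str]
    table: pd.DataFrame  # stratifier columns + n, events, rate

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f",
                          lineterminator="\n")

    def rate_at(self, **key) -> float:
        sel = self.table
        for k, v in key.items():
            sel = sel[sel[k] == v]
        if len(sel) != 1:
            raise DataError(f"stratum {key} not uniquely present")
        return float(sel["rate"].iloc[0])


def _merge_scores(scored: pd.DataFrame) -> pd.DataFrame:
    required = {"outcome"}
    if not required <= set(scored.columns):
        raise DataError("scored dataset must carry the outcome column "
                        "(merge scores with the cohort table first)")
    return scored


def attach_scores(dataset: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Join a cohort table with its score table on person_id."""
    return dataset.merge(scores, on="person_id", validate="one_to_one")


def rates_by(scored: pd.DataFrame, stratifiers: list[str],
             item_as_disease: str | None = None) -> StratifiedRates:
    """Exact event counts and proportions for each stratum combination.

    ``stratifiers`` may contain score columns (category,
    extended_category, ...), ``cohort``, ``prior_use`` or any item column
    (stratifying by presence/absence).  ``item_as_disease`` instead
    restricts to records with that item = 1 before stratifying.
    """
    scored = _merge_scores(scored)
    if not stratifiers:
        raise DataError("at least one stratifier is required")
    for s in stratifiers:
        if s not in scored.columns:
            raise DataError(f"unknown stratifier {s!r}")
    df = scored
    if item_as_disease is not None:
        if item_as_disease not in df.columns:
            raise DataError(f"unknown disease item {item_as_disease!r}")
        df = df[df[item_as_disease] == 1]
    grouped = df.groupby(stratifiers, observed=False)["outcome"].agg(["size", "sum"])
    grouped = grouped.rename(columns={"size": "n", "sum": "events"}).reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["rate"] = np.where(grouped["n"] > 0,
                                   grouped["events"] / grouped["n"], np.nan)
    grouped["events"] = grouped["events"].astype(np.int64)
    grouped["n"] = grouped["n"].astype(np.int64)
    return StratifiedRates(stratifiers=list(stratifiers), table=grouped)


def monotonicity_report(rates: StratifiedRates, ordered_stratifier: str,
                        se_multiplier: float = 2.0) -> tuple[bool, list[dict]]:
    """Is the rate non-decreasing along an ordered stratifier?

    Adjacent decreases within ``se_multiplier`` pooled binomial standard
    errors are tolerated, since sampling noise alone produces small dips.
    Returns (verdict, violations); each violation records the pair of
    strata and the magnitude of the unexplained drop.
    """
    if ordered_stratifier not in rates.stratifiers:
        raise DataError(f"{ordered_stratifier!r} is not a stratifier of this table")
    tab = rates.table[rates.table["n"] > 0].sort_values(ordered_stratifier)
    if len(tab) < 2:
        raise DataError("need at least two non-empty strata")
    verdict = True
    violations: list[dict] = []
    rows = tab.to_dict(orient="records")
    for prev, cur in zip(rows, rows[1:]):
        p_pool = (prev["events"] + cur["events"]) / (prev["n"] + cur["n"])
        se = math.sqrt(max(p_pool * (1 - p_pool), 1e-12)
                       * (1.0 / prev["n"] + 1.0 / cur["n"]))
        tol = se_multiplier * se
        if cur["rate"] < prev["rate"] - tol:
            verdict = False
            violations.append({
                "from": prev[ordered_stratifier],
                "to": cur[ordered_stratifier],
                "drop": float(prev["rate"] - cur["rate"]),
                "tolerance": float(tol),
            })
    return verdict, violations


def protective_effect_summary(scored: pd.DataFrame,
                              definition) -> dict:
    """Mean category difference, carriers vs non-carriers, at matched raw count.

    Carriers are persons with any protective item present.  When one group
    is empty the report is flagged partial instead of raising.
    """
    scored = _merge_scores(scored)
    missing = [i for i in definition.protective_items if i not in scored.columns]
    if missing:
        raise DataError(f"dataset lacks protective items: {missing}")
    if definition.protective_items:
        carrier = (scored[definition.protective_items] == 1).any(axis=1)
    else:
        carrier = pd.Series(False, index=scored.index)
    report: dict = {"per_raw_count": [], "overall_difference": None, "partial": False}
    if carrier.all() or (~carrier).all():
        report["partial"] = True
        return report
    diffs, weights = [], []
    for raw, grp in scored.groupby("raw_count"):
        has = grp[carrier.loc[grp.index]]
        not_has = grp[~carrier.loc[grp.index]]
        if len(has) == 0 or len(not_has) == 0:
            continue
        d = float(not_has["category"].mean() - has["category"].mean())
        report["per_raw_count"].append(
            {"raw_count": int(raw), "n_carriers": len(has),
             "n_noncarriers": len(not_has), "category_difference": d})
        diffs.append(d)
        weights.append(len(has))
    if diffs:
        report["overall_difference"] = float(np.average(diffs, weights=weights))
    else:
        report["partial"] = True
    return report


def prior_use_comparison(scored: pd.DataFrame) -> dict:
    """Rates over the prior-use x category grid plus the crossing indicator.

    The crossing indicator is true when persons *with* prior use but zero
    risk factors out-use persons *without* prior use at the top (6+)
    category — the signature of prior utilization dominating the clinical
    profile.
    """
    scored = _merge_scores(scored)
    for col in ("prior_use", "category"):
        if col not in scored.columns:
            raise DataError(f"scored dataset lacks {col!r}")
    if scored["prior_use"].nunique() < 2:
        raise DataError("both prior-use groups must be non-empty")
    grid = rates_by(scored, ["prior_use", "category"])
    try:
        top = int(grid.table.loc[grid.table["prior_use"] == 0, "category"].max())
        r_prior0_cat_top = grid.rate_at(prior_use=0, category=top)
        r_prior1_cat0 = grid.rate_at(prior_use=1, category=0)
    except (DataError, ValueError):
        raise DataError("grid cells required for the crossing indicator are empty")
    return {
        "grid": grid,
        "rate_prior_category0": float(r_prior1_cat0),
        "rate_noprior_top_category": float(r_prior0_cat_top),
        "crossing": bool(r_prior1_cat0 > r_prior0_cat_top),
    }


def plot_rates_by_category(rates: StratifiedRates, path, by: str = "cohort") -> None:
    """Optional bar chart of rate-by-category per cohort (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = rates.table
    fig, ax = plt.subplots(figsize=(8, 4.5))
    if by in tab.columns:
        for label, grp in tab.groupby(by):
            ax.plot(grp["category"], grp["rate"], marker="o", label=str(label))
        ax.legend(title=by, fontsize=8)
    else:
        ax.bar(tab["category"], tab["rate"])
    ax.set_xlabel("risk index category")
    ax.set_ylabel("follow-up hospital/ED rate")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
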