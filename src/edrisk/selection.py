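"""Staged stepwise covariate selection with the dual-sample retention rule.

Stage 1 runs forward selection (likelihood-ratio entry) over the screened
candidates from the clinically compelling domains — clinical complications,
disease diagnoses, specialized treatments.  After every entry, any
covariate whose adjusted OR falls below 1.2 in the derivation model *or*
in the same covariate set refit on the validation sample is pruned (and
barred from re-entry); pruning repeats until stable.  Stage 2 repeats the
procedure with the remaining six domains' candidates added to the pool.
Protective candidates are evaluated against the reciprocal threshold
(adjusted OR <= 1/1.2) since their planted effects point below 1.

The returned model is fit on the derivation sample; the full entry/drop
history is kept in ``selection_trace``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .catalog import ItemCatalog
from .errors import ConfigurationError, DataError, SeparationError
from .logistic import LogisticModel, fit_logistic
from .screening import PROTECTIVE, RISK, ScreeningResult

STAGE1_DOMAINS = frozenset({"clinical_complication", "disease", "treatment"})


@dataclass(frozen=True)
class SelectionConfig:
    stage1_domains: frozenset = STAGE1_DOMAINS
    retention_or_threshold: float = 1.2
    entry_alpha: float = 0.05
    max_terms: int = 40
    tolerance: float = 1e-8
    max_iterations: int = 100
    validation_refit: bool = True  # False: evaluate frozen derivation betas on validation

    def __post_init__(self) -> None:
        if self.retention_or_threshold <= 1.0:
            raise ConfigurationError("retention_or_threshold must exceed 1")
        if not (0.0 < self.entry_alpha < 1.0):
            raise ConfigurationError("entry_alpha must lie in (0, 1)")


@dataclass
class Candidate:
    item_id: str
    domain: str
    protective: bool


def _candidates_from_screening(screening: ScreeningResult,
                               catalog: ItemCatalog) -> list[Candidate]:
    out = []
    for row in screening.candidates.itertuples(index=False):
        out.append(Candidate(row.item_id, catalog.domain_of(row.item_id),
                             row.classification == PROTECTIVE))
    return out


def _retention_ok(or_value: float, protective: bool, threshold: float) -> bool:
    if protective:
        return or_value <= 1.0 / threshold
    return or_value >= threshold


def _validation_ors(covariates: list[str], validation: pd.DataFrame,
                    derivation_model: LogisticModel,
                    config: SelectionConfig) -> dict[str, float]:
    if config.validation_refit:
        vmod = fit_logistic(validation, covariates, config.tolerance,
                            config.max_iterations)
        return vmod.odds_ratios()
    # frozen-coefficient alternative: the derivation ORs are carried over
    return derivation_model.odds_ratios()


def stepwise_select(
    derivation: pd.DataFrame,
    validation: pd.DataFrame,
    candidates: ScreeningResult | list[Candidate],
    catalog: ItemCatalog,
    config: SelectionConfig | None = None,
) -> LogisticModel:
    """Two-stage forward selection with OR>=1.2 dual-sample retention.

    An empty candidate pool yields an intercept-only model flagged in its
    trace, not an error.
    """
    cfg = config or SelectionConfig()
    if len(derivation) == 0 or len(validation) == 0:
        raise DataError("derivation and validation samples must be non-empty")
    if isinstance(candidates, ScreeningResult):
        pool = _candidates_from_screening(candidates, catalog)
    else:
        pool = list(candidates)

    by_id = {c.item_id: c for c in pool}
    stage1 = [c.item_id for c in pool if c.domain in cfg.stage1_domains]
    stage2 = [c.item_id for c in pool if c.domain not in cfg.stage1_domains]

    trace: list[dict] = []
    selected: list[str] = []
    barred: set[str] = set()
    model = fit_logistic(derivation, [], cfg.tolerance, cfg.max_iterations)
    if not pool:
        trace.append({"event": "empty_candidate_pool"})

    for stage_no, stage_pool in ((1, stage1), (2, stage2)):
        available = [i for i in stage_pool if i not in barred and i not in selected]
        while available and len(selected) < cfg.max_terms:
            # --- entry: best LR-test candidate, if significant ---
            best_id, best_lr, best_model = None, -np.inf, None
            for item in available:
                try:
                    cand_model = fit_logistic(
                        derivation, selected + [item], cfg.tolerance,
                        cfg.max_iterations, start=model,
                    )
                except (SeparationError, DataError):
                    continue
                lr = 2.0 * (cand_model.log_likelihood - model.log_likelihood)
                if lr > best_lr:
                    best_id, best_lr, best_model = item, lr, cand_model
            if best_id is None:
                break
            p_value = float(chi2.sf(max(best_lr, 0.0), df=1))
            if p_value >= cfg.entry_alpha:
                break
            selected.append(best_id)
            model = best_model
            trace.append({"event": "enter", "stage": stage_no, "item_id": best_id,
                          "lr_statistic": float(best_lr), "p_value": p_value})
            available.remove(best_id)

            # --- retention pruning, repeated until stable ---
            while True:
                deriv_ors = model.odds_ratios()
                valid_ors = _validation_ors(selected, validation, model, cfg)
                drops = []
                for item in selected:
                    c = by_id[item]
                    ok_d = _retention_ok(deriv_ors[item], c.protective,
                                         cfg.retention_or_threshold)
                    ok_v = _retention_ok(valid_ors[item], c.protective,
                                         cfg.retention_or_threshold)
                    if not (ok_d and ok_v):
                        drops.append((item, deriv_ors[item], valid_ors[item],
                                      "derivation" if not ok_d else "validation"))
                if not drops:
                    break
                for item, od, ov, which in drops:
                    selected.remove(item)
                    barred.add(item)
                    trace.append({"event": "drop", "stage": stage_no, "item_id": item,
                                  "or_derivation": float(od), "or_validation": float(ov),
                                  "failed_in": which,
                                  "threshold": cfg.retention_or_threshold})
                model = fit_logistic(derivation, selected, cfg.tolerance,
                                     cfg.max_iterations)

    model.selection_trace = trace
    return model


def validation_refit(model: LogisticModel, validation: pd.DataFrame,
                     config: SelectionConfig | None = None) -> LogisticModel:
    """Refit the selected covariate set on the validation sample."""
    cfg = config or SelectionConfig()
    return fit_logistic(validation, model.covariates, cfg.tolerance,
                        cfg.max_iterations)
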