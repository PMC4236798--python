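"""Maximum-likelihood logistic regression via iteratively reweighted least squares.

A small, fully controlled Newton/IRLS fitter for all-dichotomous designs:
the staged selection loop needs cheap warm-started refits, explicit
convergence reporting, and early separation detection, so the solver lives
here rather than behind a generic GLM interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import expit

from .errors import DegenerateDesignError, SeparationError

#: |beta| beyond which the fit is declared separated
SEPARATION_BOUND = 15.0


@dataclass
class LogisticModel:
    """Fitted logistic model on an ordered covariate list."""

    covariates: list[str]
    intercept: float
    betas: np.ndarray  # aligned with covariates
    converged: bool
    n_iterations: int
    log_likelihood: float
    n_obs: int = 0
    selection_trace: list[dict] = field(default_factory=list)

    def odds_ratios(self) -> dict[str, float]:
        return {c: float(np.exp(b)) for c, b in zip(self.covariates, self.betas)}

    def linear_predictor(self, dataset: pd.DataFrame) -> np.ndarray:
        X = dataset[self.covariates].to_numpy(dtype=np.float64) if self.covariates \
            else np.zeros((len(dataset), 0))
        return self.intercept + X @ self.betas

    def predict_proba(self, dataset: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(dataset))

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "intercept": self.intercept,
            "betas": {c: float(b) for c, b in zip(self.covariates, self.betas)},
            "odds_ratios": self.odds_ratios(),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
            "selection_trace": self.selection_trace,
        }


def log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    """Bernoulli log-likelihood at linear predictor eta (numerically stable)."""
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(X: np.ndarray, y: np.ndarray, tol: float, max_iter: int,
          beta0: np.ndarray | None = None) -> tuple[np.ndarray, bool, int]:
    """Newton-Raphson on the full design (column 0 is the intercept)."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.astype(np.float64).copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) <= tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        XtWX = (X * w[:, None]).T @ X
        try:
            step = scipy.linalg.solve(XtWX, grad, assume_a="pos")
        except (scipy.linalg.LinAlgError, ValueError) as exc:
            raise DegenerateDesignError(f"singular information matrix: {exc}") from exc
        # damp very large Newton steps (rare; near-separated designs)
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                "coefficients diverged (|beta| > "
                f"{SEPARATION_BOUND}): perfect or quasi-perfect separation"
            )
    return beta, converged, it


def fit_logistic(
    records: pd.DataFrame,
    covariates: list[str],
    tolerance: float = 1e-8,
    max_iterations: int = 100,
    start: LogisticModel | None = None,
) -> LogisticModel:
    """Fit the logistic MLE of outcome on the given item covariates.

    Raises DegenerateDesignError when the outcome or any covariate is
    constant, and SeparationError when the MLE does not exist (diverging
    coefficients).  ``start`` warm-starts IRLS from a previous model whose
    covariates form a prefix subset of ``covariates``.
    """
    if len(records) == 0:
        raise DegenerateDesignError("empty dataset")
    y = records["outcome"].to_numpy(dtype=np.float64)
    if y.min() == y.max():
        raise DegenerateDesignError("outcome is constant")
    Xc = records[list(covariates)].to_numpy(dtype=np.float64) if covariates \
        else np.zeros((len(records), 0))
    for j, name in enumerate(covariates):
        col = Xc[:, j]
        if col.min() == col.max():
            raise DegenerateDesignError(f"covariate {name!r} is constant")
    X = np.column_stack([np.ones(len(records)), Xc])

    beta0 = None
    if start is not None:
        prev = dict(zip(start.covariates, start.betas))
        beta0 = np.array([start.intercept] + [prev.get(c, 0.0) for c in covariates])

    beta, converged, n_iter = _irls(X, y, tolerance, max_iterations, beta0)
    ll = log_likelihood(y, X @ beta)
    return LogisticModel(
        covariates=list(covariates),
        intercept=float(beta[0]),
        betas=beta[1:].copy(),
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=ll,
        n_obs=len(records),
    )
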