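"""Regression equations consumed by the G-computation step.

Two families are supported, matching the mediation pipeline's needs:

* ``gaussian`` (identity link) — the mediator equation, fitted by ordinary
  least squares; used both for the raw mediator score and, as a linear
  probability model, for a dichotomised mediator.
* ``binomial`` (logit link) — the outcome equation, fitted by iteratively
  reweighted least squares (IRLS) to the maximum-likelihood solution.

Fitting is deliberately lightweight: the bootstrap refits both equations
thousands of times, so each fit is a handful of dense linear solves.
Inference on individual coefficients (Wald z, CI) comes from the estimated
coefficient covariance — sigma^2 (X'X)^-1 for gaussian, the inverse observed
information (X'WX)^-1 for binomial.  Confidence intervals for the mediation
effects themselves come from the bootstrap, not from these fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DesignSpec",
    "FittedModel",
    "CoefficientTest",
    "GlmError",
    "RankDeficientError",
    "fit",
    "predict_linear",
    "coefficient_test",
    "expand_categoricals",
]

MAX_IRLS_ITER = 100
SCORE_TOL = 1e-8


class GlmError(ValueError):
    pass


class RankDeficientError(GlmError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear "
                         f"column(s): {self.columns}")


@dataclass(frozen=True)
class DesignSpec:
    """One regression equation: response ~ terms (+ intercept)."""

    response: str
    terms: tuple[str, ...]
    family: str = "gaussian"  # "gaussian" | "binomial"
    include_intercept: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(set(self.terms)) != len(self.terms):
            raise GlmError("duplicate terms in design")
        if self.response in self.terms:
            raise GlmError("response cannot appear among the terms")
        if self.family not in ("gaussian", "binomial"):
            raise GlmError(f"unknown family {self.family!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        return (("intercept",) if self.include_intercept else ()) + self.terms


@dataclass
class FittedModel:
    """Coefficients and metadata for one fitted equation."""

    spec: DesignSpec
    params: np.ndarray                 # aligned with spec.param_names
    cov_params: np.ndarray
    n_obs: int
    loglik: float
    converged: bool
    residual_sd: float | None = None   # gaussian only
    n_iter: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.spec.param_names, map(float, self.params)))

    def to_dict(self) -> dict:
        out = {
            "response": self.spec.response,
            "family": self.spec.family,
            "coefficients": self.coefficients,
            "n_obs": self.n_obs,
            "loglik": self.loglik,
            "converged": self.converged,
        }
        if self.residual_sd is not None:
            out["residual_sd"] = self.residual_sd
        return out


@dataclass(frozen=True)
class CoefficientTest:
    term: str
    beta: float
    se: float
    z: float | None
    p: float | None
    ci95: tuple[float, float]


def _design_matrix(spec: DesignSpec, data: pd.DataFrame) -> np.ndarray:
    missing = [t for t in spec.terms if t not in data.columns]
    if missing:
        raise GlmError(f"missing design column(s): {missing}")
    cols = [np.asarray(data[t], dtype=float) for t in spec.terms]
    if spec.include_intercept:
        cols.insert(0, np.ones(len(data)))
    return np.column_stack(cols) if cols else np.empty((len(data), 0))


def _check_rank(x: np.ndarray, names) -> None:
    if x.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    # identify a minimal culprit set by greedy column scan
    collinear = []
    kept: list[int] = []
    for j in range(x.shape[1]):
        trial = x[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            collinear.append(names[j])
    raise RankDeficientError(collinear)


def fit(spec: DesignSpec, data: pd.DataFrame) -> FittedModel:
    """Fit one equation; OLS for gaussian, IRLS maximum likelihood for
    binomial.  Non-convergence (e.g. perfect separation) is surfaced via
    ``converged=False`` and a warning entry, never silently."""
    y = np.asarray(data[spec.response], dtype=float)
    x = _design_matrix(spec, data)
    n, p = x.shape
    if n <= p:
        raise GlmError(f"n_obs={n} must exceed n_params={p}")
    names = spec.param_names
    _check_rank(x, names)

    if spec.family == "gaussian":
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        rss = float(resid @ resid)
        sigma2 = rss / (n - p)
        xtx_inv = np.linalg.inv(x.T @ x)
        cov = sigma2 * xtx_inv
        # gaussian loglik at the MLE variance rss/n
        s2_ml = max(rss / n, 1e-300)
        loglik = -0.5 * n * (np.log(2 * np.pi * s2_ml) + 1.0)
        return FittedModel(spec=spec, params=beta, cov_params=cov, n_obs=n,
                           loglik=float(loglik), converged=True,
                           residual_sd=float(np.sqrt(sigma2)))

    if not np.isin(y, (0.0, 1.0)).all():
        raise GlmError("binomial response must be coded 0/1")
    beta = np.zeros(p)
    converged = False
    warnings: list[str] = []
    it = 0
    for it in range(1, MAX_IRLS_ITER + 1):
        eta = x @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        score = x.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        xtwx = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            warnings.append("singular information matrix during IRLS")
            break
        # dampen absurd steps (separation drives |beta| to infinity)
        beta = beta + np.clip(step, -50, 50)
        if np.max(np.abs(beta)) > 1e4:
            warnings.append("coefficients diverging; possible perfect separation")
            break
    eta = x @ beta
    mu = np.clip(special.expit(eta), 1e-12, 1 - 1e-12)
    loglik = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
    if converged and loglik > -1e-4 and p > 1:
        # zero deviance: the likelihood has no interior maximum
        converged = False
        warnings.append("perfect separation: deviance is numerically zero")
    w = mu * (1.0 - mu)
    xtwx = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if not converged and not warnings:
        warnings.append("IRLS did not converge within iteration budget")
    return FittedModel(spec=spec, params=beta, cov_params=cov, n_obs=n,
                       loglik=loglik, converged=converged, n_iter=it,
                       warnings=warnings)


def predict_linear(model: FittedModel, records: pd.DataFrame) -> np.ndarray:
    """Linear predictor eta for each record (logit scale for binomial)."""
    x = _design_matrix(model.spec, records)
    return x @ model.params


def coefficient_test(model: FittedModel, term: str) -> CoefficientTest:
    """Wald test for one coefficient from the estimated covariance."""
    names = model.spec.param_names
    if term not in names:
        raise GlmError(f"term {term!r} not in model ({names})")
    j = names.index(term)
    beta = float(model.params[j])
    se = float(np.sqrt(model.cov_params[j, j]))
    if not model.converged:
        # statistics still reported, flagged upstream via model.warnings
        pass
    if se == 0.0:
        return CoefficientTest(term, beta, se, None, None, (beta, beta))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    half = 1.959963984540054 * se
    return CoefficientTest(term, beta, se, float(z), float(p),
                           (beta - half, beta + half))


def expand_categoricals(data: pd.DataFrame, columns) -> tuple[pd.DataFrame, dict]:
    """Reference-code string/categorical columns into indicator columns.

    The reference level is the most frequent level (ties broken
    alphabetically); the mapping is returned for logging.
    """
    out = data.copy()
    mapping: dict[str, dict] = {}
    for col in columns:
        if col not in out.columns:
            continue
        if pd.api.types.is_numeric_dtype(out[col]):
            continue
        counts = out[col].value_counts()
        top = counts.max()
        reference = sorted(counts[counts == top].index)[0]
        levels = [lv for lv in sorted(out[col].dropna().unique()) if lv != reference]
        new_cols = []
        for lv in levels:
            name = f"{col}_{lv}"
            out[name] = (out[col] == lv).astype(float)
            new_cols.append(name)
        out = out.drop(columns=col)
        mapping[col] = {"reference": reference, "indicators": new_cols}
    return out, mapping
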