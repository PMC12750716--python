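"""Monte Carlo G-computation of natural mediation effects.

The estimand decomposition, on the risk-difference scale, is

* TCE = E[Y(1, M(1))] - E[Y(0, M(0))]  — total causal effect,
* NDE = E[Y(1, M(0))] - E[Y(0, M(0))]  — natural direct effect, with the
  mediator held at the level it would take without exposure,
* NIE = TCE - NDE                       — natural indirect (mediated) effect,
* proportion mediated = NIE / TCE (undefined when TCE is zero).

Counterfactual outcome means are computed by standardization over the
observed confounder distribution: for every record, the mediator is drawn
``mc_draws`` times from its fitted equation with the exposure forced to the
required level, and the outcome probability is then evaluated from the
fitted logistic outcome equation at each (exposure setting, mediator draw,
observed confounders) triple.  By default the outcome expectation is taken
analytically (averaging predicted probabilities); Monte Carlo error enters
through the mediator draws only.  A ``draw_y`` mode that samples Bernoulli
outcomes instead is available as a fidelity check.

The same M(0) draws are used for both E[Y(0, M(0))] and E[Y(1, M(0))]
(common random numbers), so NIE + NDE = TCE holds exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special

from . import dag as dagmod
from . import glm

__all__ = [
    "MediationConfig",
    "CounterfactualMeans",
    "MediationEstimates",
    "MediationResult",
    "EstimationError",
    "simulate_mediator",
    "counterfactual_means",
    "decompose",
    "estimate",
]

PROP_MEDIATED_TCE_FLOOR = 1e-10
LPM_CLIP = (1e-6, 1.0 - 1e-6)


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MediationConfig:
    """Configuration of one mediation estimation run."""

    exposure: str = "x_helpful"
    outcome: str = "y_exclusive"
    mediator_raw: str = "bses_total"
    mediator_binary: str = "m_bses_high"
    mediator_scale: str = "raw"        # "raw" | "binary"
    mediator_family: str = "gaussian"  # binary mediator: "gaussian" = linear
                                       # probability model, or "binomial"
    mc_draws: int = 100
    draw_y: bool = False
    interaction: bool = False
    adjustment_outcome: tuple[str, ...] | None = None
    adjustment_mediator: tuple[str, ...] | None = None

    @property
    def mediator(self) -> str:
        return self.mediator_raw if self.mediator_scale == "raw" else self.mediator_binary

    @property
    def mediator_kind(self) -> str:
        if self.mediator_scale == "raw":
            return "continuous"
        return "binary_lpm" if self.mediator_family == "gaussian" else "binary_logit"

    def __post_init__(self) -> None:
        if self.mediator_scale not in ("raw", "binary"):
            raise ValueError("mediator_scale must be 'raw' or 'binary'")
        if self.mediator_family not in ("gaussian", "binomial"):
            raise ValueError("mediator_family must be 'gaussian' or 'binomial'")
        if self.mc_draws < 1:
            raise ValueError("mc_draws must be >= 1")


@dataclass(frozen=True)
class CounterfactualMeans:
    """Counterfactual outcome probabilities under the three regimes."""

    mu_11: float  # E[Y(1, M(1))]
    mu_00: float  # E[Y(0, M(0))]
    mu_10: float  # E[Y(1, M(0))]

    def __post_init__(self) -> None:
        for name in ("mu_11", "mu_00", "mu_10"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass(frozen=True)
class MediationEstimates:
    tce: float
    nde: float
    nie: float
    prop_mediated: float | None  # None when TCE is (numerically) zero

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MediationResult:
    estimates: MediationEstimates
    means: CounterfactualMeans
    model_m: glm.FittedModel
    model_y: glm.FittedModel
    adjustment_outcome: list[str]
    adjustment_mediator: list[str]
    n_obs: int
    mc_draws: int
    n_lpm_clipped: int = 0

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.to_dict(),
            "counterfactual_means": asdict(self.means),
            "adjustment_outcome": self.adjustment_outcome,
            "adjustment_mediator": self.adjustment_mediator,
            "n_obs": self.n_obs,
            "mc_draws": self.mc_draws,
            "n_lpm_clipped": self.n_lpm_clipped,
            "model_m": self.model_m.to_dict(),
            "model_y": self.model_y.to_dict(),
        }


def simulate_mediator(
    model_m: glm.FittedModel,
    records: pd.DataFrame,
    x_set: int,
    draws: int,
    rng: np.random.Generator,
    exposure: str = "x_helpful",
    kind: str = "continuous",
) -> tuple[np.ndarray, int]:
    """Draw the mediator for every record with the exposure forced to
    ``x_set``.

    Returns an ``(n_records, draws)`` array and the number of
    linear-probability predictions that had to be clipped into (0, 1).
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    if not model_m.converged:
        raise EstimationError("mediator model did not converge")
    frame = records.copy()
    frame[exposure] = float(x_set)
    eta = glm.predict_linear(model_m, frame)  # (n,)
    n = len(frame)
    n_clipped = 0
    if kind == "continuous":
        sd = model_m.residual_sd if model_m.residual_sd is not None else 0.0
        noise = rng.standard_normal((n, draws)) * sd if sd > 0 else 0.0
        out = eta[:, None] + noise
        if np.isscalar(out) or out.shape != (n, draws):
            out = np.broadcast_to(eta[:, None], (n, draws)).copy()
    elif kind == "binary_lpm":
        p = eta
        n_clipped = int(np.sum((p < LPM_CLIP[0]) | (p > LPM_CLIP[1])))
        p = np.clip(p, *LPM_CLIP)
        out = (rng.random((n, draws)) < p[:, None]).astype(float)
    elif kind == "binary_logit":
        p = special.expit(eta)
        out = (rng.random((n, draws)) < p[:, None]).astype(float)
    else:
        raise ValueError(f"unknown mediator kind {kind!r}")
    return np.asarray(out, dtype=float), n_clipped


def _y_components(model_y: glm.FittedModel, records: pd.DataFrame,
                  exposure: str, mediator: str) -> tuple[np.ndarray, float, float, float]:
    """Split the outcome linear predictor into (confounder baseline,
    exposure coefficient, mediator coefficient, interaction coefficient)."""
    frame = records.copy()
    frame[exposure] = 0.0
    frame[mediator] = 0.0
    inter = f"{exposure}:{mediator}"
    if inter in model_y.spec.terms:
        frame[inter] = 0.0
    base = glm.predict_linear(model_y, frame)
    coefs = model_y.coefficients
    return base, coefs[exposure], coefs[mediator], coefs.get(inter, 0.0)


def counterfactual_means(
    model_y: glm.FittedModel,
    model_m: glm.FittedModel,
    records: pd.DataFrame,
    draws: int,
    rng: np.random.Generator,
    exposure: str = "x_helpful",
    mediator: str = "bses_total",
    mediator_kind: str = "continuous",
    draw_y: bool = False,
) -> tuple[CounterfactualMeans, int]:
    """Standardized counterfactual outcome means over the observed
    confounder distribution.

    Returns the three means and the count of clipped linear-probability
    mediator predictions (zero unless ``mediator_kind='binary_lpm'``).
    """
    if not model_y.converged:
        raise EstimationError("outcome model did not converge")
    m0, c0 = simulate_mediator(model_m, records, 0, draws, rng,
                               exposure=exposure, kind=mediator_kind)
    m1, c1 = simulate_mediator(model_m, records, 1, draws, rng,
                               exposure=exposure, kind=mediator_kind)
    base, b_x, b_m, b_xm = _y_components(model_y, records, exposure, mediator)
    b = base[:, None]

    p11 = special.expit(b + b_x + (b_m + b_xm) * m1)
    p10 = special.expit(b + b_x + (b_m + b_xm) * m0)
    p00 = special.expit(b + b_m * m0)
    if draw_y:
        p11 = (rng.random(p11.shape) < p11).astype(float)
        p10 = (rng.random(p10.shape) < p10).astype(float)
        p00 = (rng.random(p00.shape) < p00).astype(float)
    means = CounterfactualMeans(
        mu_11=float(np.mean(p11)),
        mu_00=float(np.mean(p00)),
        mu_10=float(np.mean(p10)),
    )
    return means, c0 + c1


def decompose(means: CounterfactualMeans) -> MediationEstimates:
    """Effect decomposition on the risk-difference scale.

    NIE is defined as TCE - NDE, so the decomposition identity holds exactly
    for every input; the proportion mediated is left undefined (``None``)
    when |TCE| is numerically zero rather than propagating a NaN.
    """
    tce = means.mu_11 - means.mu_00
    nde = means.mu_10 - means.mu_00
    nie = tce - nde
    prop = nie / tce if abs(tce) >= PROP_MEDIATED_TCE_FLOOR else None
    return MediationEstimates(tce=tce, nde=nde, nie=nie, prop_mediated=prop)


def _resolve_adjustment(
    data: pd.DataFrame,
    causal_dag: dagmod.CausalDAG | None,
    config: MediationConfig,
) -> tuple[list[str], list[str]]:
    if config.adjustment_outcome is not None and config.adjustment_mediator is not None:
        return list(config.adjustment_outcome), list(config.adjustment_mediator)
    if causal_dag is None:
        raise EstimationError(
            "either a causal DAG or explicit adjustment sets are required"
        )
    sets = dagmod.adjustment_sets(causal_dag)
    adj_y = (list(config.adjustment_outcome)
             if config.adjustment_outcome is not None
             else dagmod.select_adjustment_set(sets.for_outcome_equation))
    adj_m = (list(config.adjustment_mediator)
             if config.adjustment_mediator is not None
             else dagmod.select_adjustment_set(sets.for_mediator_equation))
    return adj_y, adj_m


def estimate(
    data: pd.DataFrame,
    causal_dag: dagmod.CausalDAG | None,
    config: MediationConfig,
    rng: np.random.Generator | int | None = None,
) -> MediationResult:
    """Run the full G-computation pipeline on a derived analysis table.

    Fits the mediator equation (linear by default) and the logistic outcome
    equation on their minimal sufficient adjustment sets, simulates the
    counterfactual mediator, standardizes the outcome, and decomposes the
    effect.  Deterministic given the generator/seed passed as ``rng``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    adj_y, adj_m = _resolve_adjustment(data, causal_dag, config)
    for col in set(adj_y) | set(adj_m):
        if col not in data.columns:
            raise EstimationError(f"adjustment variable {col!r} not in data")

    mediator = config.mediator
    m_family = ("gaussian" if config.mediator_scale == "raw"
                else config.mediator_family)
    spec_m = glm.DesignSpec(response=mediator,
                            terms=tuple([config.exposure] + adj_m),
                            family=m_family)
    y_terms = [config.exposure, mediator]
    frame = data
    if config.interaction:
        inter = f"{config.exposure}:{mediator}"
        frame = data.copy()
        frame[inter] = frame[config.exposure] * frame[mediator]
        y_terms.append(inter)
    spec_y = glm.DesignSpec(response=config.outcome,
                            terms=tuple(y_terms + adj_y),
                            family="binomial")

    model_m = glm.fit(spec_m, frame)
    model_y = glm.fit(spec_y, frame)
    for name, model in (("mediator", model_m), ("outcome", model_y)):
        if not model.converged:
            raise EstimationError(
                f"{name} model failed to converge: {model.warnings}"
            )

    means, n_clipped = counterfactual_means(
        model_y, model_m, frame, config.mc_draws, rng,
        exposure=config.exposure, mediator=mediator,
        mediator_kind=config.mediator_kind, draw_y=config.draw_y,
    )
    return MediationResult(
        estimates=decompose(means),
        means=means,
        model_m=model_m,
        model_y=model_y,
        adjustment_outcome=adj_y,
        adjustment_mediator=adj_m,
        n_obs=len(data),
        mc_draws=config.mc_draws,
        n_lpm_clipped=n_clipped,
    )
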