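"""Nonparametric bootstrap of the mediation pipeline.

Participant records are resampled with replacement; the entire estimation
pipeline (refit of the mediator and outcome equations, fresh counterfactual
simulation) is rerun on every resample.  Per estimand the summary mirrors a
standard mediation results table: point estimate, bootstrap SE (sample SD of
the replicates), z = estimate/SE with a normal two-sided p-value, a normal
95% interval (point +/- 1.96 SE), and Efron's bias-corrected (BC) percentile
interval

    z0 = Phi^-1( (#{theta* < theta_hat} + 0.5 #{theta* = theta_hat}) / B )
    bounds at the empirical Phi(2 z0 +/- z_alpha) quantiles,

with quantiles taken by the nearest-rank rule.  BC (not BCa) is used: no
acceleration constant.  Replicate seeds are derived from the master seed by
counter so a failed replicate does not shift the stream of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import dag as dagmod
from .gcomp import MediationConfig, MediationResult, estimate

__all__ = [
    "BootstrapResult",
    "InferenceTable",
    "BootstrapError",
    "bootstrap",
    "bc_interval",
    "wald_summary",
]

MAX_FAILED_FRACTION = 0.05
Z975 = 1.959963984540054

ESTIMANDS = ("tce", "nde", "nie")


class BootstrapError(RuntimeError):
    pass


def wald_summary(point: float, se: float) -> tuple[float | None, float | None]:
    """z = point/se and two-sided normal p; undefined (None) when se = 0."""
    if se < 0:
        raise ValueError("se must be >= 0")
    if se == 0.0:
        return None, None
    z = point / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def _nearest_rank_quantile(sorted_reps: np.ndarray, q: float) -> float:
    b = len(sorted_reps)
    k = int(np.ceil(q * b))
    return float(sorted_reps[min(max(k, 1), b) - 1])


def bc_interval(
    replicates: np.ndarray,
    point: float,
    level: float = 0.95,
) -> tuple[tuple[float, float], dict]:
    """Efron bias-corrected percentile interval.

    Returns ``((lo, hi), info)`` where ``info`` records z0 and whether the
    bias fraction had to be clamped away from 0 or 1 (which happens when the
    point estimate falls outside the whole replicate cloud).  All-identical
    replicates give the degenerate interval ``(point, point)``.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if not np.isfinite(reps).all():
        raise ValueError("non-finite bootstrap replicates")
    b = reps.size
    if np.all(reps == reps[0]) and reps[0] == point:
        return (point, point), {"z0": 0.0, "clamped": False}
    frac = (np.sum(reps < point) + 0.5 * np.sum(reps == point)) / b
    clamped = False
    if frac <= 0.0:
        frac, clamped = 0.5 / b, True
    elif frac >= 1.0:
        frac, clamped = 1.0 - 0.5 / b, True
    z0 = float(stats.norm.ppf(frac))
    za = stats.norm.ppf((1.0 - level) / 2.0)  # negative
    q_lo = float(stats.norm.cdf(2.0 * z0 + za))
    q_hi = float(stats.norm.cdf(2.0 * z0 - za))
    sorted_reps = np.sort(reps)
    lo = _nearest_rank_quantile(sorted_reps, q_lo)
    hi = _nearest_rank_quantile(sorted_reps, q_hi)
    return (lo, hi), {"z0": z0, "clamped": clamped}


@dataclass
class BootstrapResult:
    estimand: str
    point: float
    replicates: np.ndarray
    se: float
    z: float | None
    p: float | None
    ci_normal: tuple[float, float]
    ci_bc: tuple[float, float]
    b_requested: int
    b_failed: int
    bc_info: dict = field(default_factory=dict)

    def to_dict(self, include_replicates: bool = False) -> dict:
        out = {
            "estimand": self.estimand,
            "point": self.point,
            "se": self.se,
            "z": self.z,
            "p": self.p,
            "ci_normal": list(self.ci_normal),
            "ci_bc": list(self.ci_bc),
            "b_requested": self.b_requested,
            "b_failed": self.b_failed,
        }
        if include_replicates:
            out["replicates"] = [float(v) for v in self.replicates]
        return out


@dataclass
class InferenceTable:
    """Machine-readable results table: one row per estimand."""

    results: dict[str, BootstrapResult]
    prop_mediated: float | None
    point_result: MediationResult

    def to_dict(self, include_replicates: bool = False) -> dict:
        return {
            "estimands": {k: r.to_dict(include_replicates)
                          for k, r in self.results.items()},
            "prop_mediated": self.prop_mediated,
        }

    def to_text(self, title: str = "G-computation mediation estimates") -> str:
        header = (f"{'':>5} {'G-estimate':>10} {'Boot SE':>8} {'z':>6} "
                  f"{'p':>6} {'95% CI':>16} {'95% CI (BC)':>16}")
        lines = [title, "=" * len(header), header, "-" * len(header)]
        for name in ESTIMANDS:
            r = self.results[name]
            z = f"{r.z:.2f}" if r.z is not None else "--"
            p = f"{r.p:.2f}" if r.p is not None else "--"
            ci = f"{r.ci_normal[0]:.2f} to {r.ci_normal[1]:.2f}"
            bc = f"{r.ci_bc[0]:.2f} to {r.ci_bc[1]:.2f}"
            lines.append(f"{name.upper():>5} {r.point:>10.2f} {r.se:>8.2f} "
                         f"{z:>6} {p:>6} {ci:>16} {bc:>16}")
        if self.prop_mediated is not None:
            lines.append(f"Proportion mediated: {100 * self.prop_mediated:.0f}%")
        else:
            lines.append("Proportion mediated: undefined (TCE = 0)")
        return "\n".join(lines)


def _replicate_rng(master_seed: int, counter: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(counter,))
    )


def bootstrap(
    data: pd.DataFrame,
    causal_dag: dagmod.CausalDAG | None,
    config: MediationConfig,
    b: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> InferenceTable:
    """Bootstrap the full pipeline: B resamples of n records with
    replacement, refit + re-simulate per resample.

    Replicates whose models fail to converge are dropped and counted; the
    run aborts when more than 5% fail, since silently discarding many
    replicates biases the intervals.
    """
    if b < 2:
        raise ValueError("need at least B=2 bootstrap samples")
    point_result = estimate(data, causal_dag, config,
                            rng=_replicate_rng(seed, 0))
    points = {k: getattr(point_result.estimates, k) for k in ESTIMANDS}

    # the adjustment sets are selected once, on the full data's DAG, and
    # held fixed across resamples (resampling does not change the graph)
    config = replace(
        config,
        adjustment_outcome=tuple(point_result.adjustment_outcome),
        adjustment_mediator=tuple(point_result.adjustment_mediator))

    n = len(data)
    reps: dict[str, list[float]] = {k: [] for k in ESTIMANDS}
    b_failed = 0
    for i in range(1, b + 1):
        rng = _replicate_rng(seed, i)
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            res = estimate(sample, causal_dag, config, rng=rng)
        except Exception:
            b_failed += 1
            continue
        for k in ESTIMANDS:
            reps[k].append(getattr(res.estimates, k))
    if b_failed / b > MAX_FAILED_FRACTION:
        raise BootstrapError(
            f"{b_failed}/{b} bootstrap replicates failed to converge; "
            f"refusing to report biased intervals"
        )

    results: dict[str, BootstrapResult] = {}
    for k in ESTIMANDS:
        arr = np.asarray(reps[k], dtype=float)
        se = float(np.std(arr, ddof=1))
        z, p = wald_summary(points[k], se)
        ci_n = (points[k] - Z975 * se, points[k] + Z975 * se)
        ci_bc, info = bc_interval(arr, points[k], level=level)
        results[k] = BootstrapResult(
            estimand=k, point=points[k], replicates=arr, se=se, z=z, p=p,
            ci_normal=ci_n, ci_bc=ci_bc, b_requested=b, b_failed=b_failed,
            bc_info=info,
        )
    return InferenceTable(
        results=results,
        prop_mediated=point_result.estimates.prop_mediated,
        point_result=point_result,
    )
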