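"""End-to-end orchestration: config -> derive -> adjust -> estimate ->
bootstrap -> report.

A run is described by a TOML configuration file::

    [paths]
    data = "cohort.csv"        # omit when [synthetic] is present
    dag = "model.dag"
    out_dir = "results"

    [columns]                  # optional logical-name -> CSV-column map
    x_helpful = "nurse_help_bin"

    [analysis]
    mediator_scale = "raw"     # "raw" | "binary"
    mediator_family = "gaussian"
    mc_draws = 100
    bootstrap_b = 1000
    seed = 20250101
    ci_level = 0.95
    subsample = "first_visit"  # "first_visit" | "repeat_visit"
    interaction = false
    draw_y = false
    adjustment_outcome = ["age", ...]   # optional override of the DAG choice
    adjustment_mediator = ["age", ...]

    [synthetic]                # generate a cohort instead of reading one
    preset = "study"           # "study" | "recovery"
    n = 169

Outputs written to ``out_dir``: ``derived.csv``, ``exclusions.json``,
``adjustment.json``, ``inference.json``, ``inference.txt``,
``descriptives.json`` and ``manifest.json``.  The input CSV is never
modified.  Given the same config and seed, the JSON outputs are
byte-identical across runs (the manifest carries no timestamps).
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dag as dagmod, derive, simulate
from .inference import bootstrap
from .gcomp import MediationConfig

__all__ = ["RunConfig", "run", "summarize_descriptives", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    data_path: str | None = None
    dag_path: str | None = None
    out_dir: str = "results"
    column_map: dict = field(default_factory=dict)
    mediator_scale: str = "raw"
    mediator_family: str = "gaussian"
    mc_draws: int = 100
    bootstrap_b: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    subsample: str = "first_visit"
    interaction: bool = False
    draw_y: bool = False
    adjustment_outcome: list | None = None
    adjustment_mediator: list | None = None
    confounders: list = field(
        default_factory=lambda: list(derive.DEFAULT_CONFOUNDERS))
    synthetic: dict | None = None

    def __post_init__(self) -> None:
        if self.bootstrap_b < 2:
            raise ValueError("bootstrap_b must be >= 2")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0,1)")
        if self.subsample not in ("first_visit", "repeat_visit"):
            raise ValueError("subsample must be 'first_visit' or 'repeat_visit'")

    def mediation_config(self) -> MediationConfig:
        return MediationConfig(
            mediator_scale=self.mediator_scale,
            mediator_family=self.mediator_family,
            mc_draws=self.mc_draws,
            draw_y=self.draw_y,
            interaction=self.interaction,
            adjustment_outcome=(tuple(self.adjustment_outcome)
                                if self.adjustment_outcome is not None else None),
            adjustment_mediator=(tuple(self.adjustment_mediator)
                                 if self.adjustment_mediator is not None else None),
        )

    def echo(self) -> dict:
        out = {k: v for k, v in self.__dict__.items()}
        return json.loads(json.dumps(out, default=str))


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    paths = raw.get("paths", {})
    analysis = raw.get("analysis", {})
    return RunConfig(
        data_path=paths.get("data"),
        dag_path=paths.get("dag"),
        out_dir=paths.get("out_dir", "results"),
        column_map=raw.get("columns", {}),
        synthetic=raw.get("synthetic"),
        **{k: analysis[k] for k in (
            "mediator_scale", "mediator_family", "mc_draws", "bootstrap_b",
            "seed", "ci_level", "subsample", "interaction", "draw_y",
            "adjustment_outcome", "adjustment_mediator", "confounders",
        ) if k in analysis},
    )


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float)
                    + "\n")


def summarize_descriptives(table: pd.DataFrame) -> dict:
    """Cohort-characteristics block: mean (SD) for continuous variables,
    n (%) for binary/categorical, median (IQR) for infant age and the
    self-efficacy score."""
    out: dict = {"n": int(len(table))}
    continuous = [c for c in ("age", "assets") if c in table.columns]
    binary = [c for c in ("x_helpful", "m_bses_high", "y_exclusive",
                          "caesarean", "educ_grade12", "employed", "hiv",
                          "hps_high", "hsi_high") if c in table.columns]
    skewed = [c for c in ("infant_age", "bses_total", "parity")
              if c in table.columns]
    for c in continuous:
        v = table[c].astype(float)
        out[c] = {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
    for c in binary:
        v = table[c].astype(float)
        out[c] = {"n": int(v.sum()), "pct": float(100.0 * v.mean())}
    for c in skewed:
        v = table[c].astype(float)
        q1, med, q3 = (float(np.quantile(v, q)) for q in (0.25, 0.5, 0.75))
        out[c] = {"median": med, "iqr": [q1, q3]}
    return out


def _load_table(config: RunConfig) -> pd.DataFrame:
    if config.synthetic is not None:
        preset = config.synthetic.get("preset", "study")
        n = int(config.synthetic.get("n", 169))
        factory = {"study": simulate.study_config,
                   "recovery": simulate.recovery_config}.get(preset)
        if factory is None:
            raise PipelineError("load", f"unknown synthetic preset {preset!r}")
        return simulate.generate(factory(n), seed=config.seed)
    if config.data_path is None:
        raise PipelineError("load", "config needs paths.data or a [synthetic] block")
    return pd.read_csv(config.data_path)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write the result bundle.

    Returns a dict with the main in-memory artefacts (derived table,
    exclusion log, adjustment report, inference table, output paths).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        raw = _load_table(config)

        try:
            derived, exclusion_log = derive.derive_table(
                raw, column_map=config.column_map,
                confounders=config.confounders)
        except derive.ValidationError as exc:
            raise PipelineError("derive", str(exc)) from exc

        if "visit" in derived.columns:
            wanted = "first" if config.subsample == "first_visit" else "repeat"
            derived = derived[derived["visit"] == wanted].reset_index(drop=True)
        elif config.subsample == "repeat_visit":
            raise PipelineError("subsample",
                                "no 'visit' column; cannot select repeat visits")

        causal_dag = None
        adjustment_report: dict = {"source": "config_override"}
        if config.dag_path is not None:
            try:
                causal_dag = dagmod.read_dag(Path(config.dag_path).read_text())
            except dagmod.DagError as exc:
                raise PipelineError("adjust", str(exc)) from exc
            sets = dagmod.adjustment_sets(causal_dag)
            adjustment_report = {
                "source": "dag",
                "minimal_sets_outcome": [sorted(s) for s in
                                         sets.for_outcome_equation],
                "minimal_sets_mediator": [sorted(s) for s in
                                          sets.for_mediator_equation],
            }
        mcfg = config.mediation_config()
        if causal_dag is None and (mcfg.adjustment_outcome is None
                                   or mcfg.adjustment_mediator is None):
            raise PipelineError("adjust",
                                "need a DAG file or explicit adjustment sets")

        try:
            table = bootstrap(derived, causal_dag, mcfg,
                              b=config.bootstrap_b, seed=config.seed,
                              level=config.ci_level)
        except Exception as exc:
            raise PipelineError("bootstrap", str(exc)) from exc
        point = table.point_result
        adjustment_report["used_outcome"] = point.adjustment_outcome
        adjustment_report["used_mediator"] = point.adjustment_mediator

        derived_path = out_dir / "derived.csv"
        derived.to_csv(derived_path, index=False)
        written.append(derived_path)
        for name, payload in (
            ("exclusions.json", exclusion_log),
            ("adjustment.json", adjustment_report),
            ("descriptives.json", summarize_descriptives(derived)),
            ("inference.json", {
                "table": table.to_dict(),
                "point": point.to_dict(),
            }),
            ("manifest.json", {
                "package": "gmediate",
                "version": __version__,
                "seed": config.seed,
                "mc_draws": config.mc_draws,
                "bootstrap_b": config.bootstrap_b,
                "config": config.echo(),
            }),
        ):
            path = out_dir / name
            _json_dump(payload, path)
            written.append(path)
        text_path = out_dir / "inference.txt"
        text_path.write_text(table.to_text() + "\n")
        written.append(text_path)
    except Exception:
        for path in written:  # no partial bundles
            path.unlink(missing_ok=True)
        raise
    return {
        "derived": derived,
        "exclusions": exclusion_log,
        "adjustment": adjustment_report,
        "inference": table,
        "out_dir": out_dir,
        "files": [str(p) for p in written],
    }
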