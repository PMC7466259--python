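"""End-to-end orchestration: responses -> models -> desirability optimum.

The pipeline reproduces a complete method-development analysis from a
response table alone: identify the center replicates, recover the
run-to-combination assignment (when reference models are available), fit
the full second-order model to every response, flag significant terms,
optimize the composite desirability, and classify the predicted
resolutions at the optimum. Deterministic: the same config and inputs
yield byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import desirability as des
from . import doe, rsm
from .peaks import ResponseTable, classify_separation

logger = logging.getLogger("chromopt")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    factors: list
    n_center: int = 3
    fop_encoding: float = 0.0
    alpha: float = 0.05
    goals: list | None = None  # None -> threshold defaults
    anchor_mode: str = "threshold"  # or "observed"
    use_reduced_models: bool = False
    grid_n: int = 201
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.anchor_mode not in ("threshold", "observed"):
            raise ValueError("anchor_mode must be 'threshold' or 'observed'")

    def digest(self) -> str:
        blob = json.dumps(
            {
                "factors": [(f.name, f.low, f.high) for f in self.factors],
                "n_center": self.n_center,
                "fop_encoding": self.fop_encoding,
                "alpha": self.alpha,
                "anchor_mode": self.anchor_mode,
                "use_reduced_models": self.use_reduced_models,
                "grid_n": self.grid_n,
                "seed": self.seed,
                "goals": None
                if self.goals is None
                else [
                    (g.response_name, g.direction, g.low, g.high, g.shape, g.impact)
                    for g in self.goals
                ],
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    responses: ResponseTable,
    design: doe.Design | None = None,
    reference_models: list[rsm.QuadraticModel] | None = None,
) -> dict:
    """Run the full analysis and return a report bundle (plain dict).

    Either an explicit ``design`` (runs in table order) or
    ``reference_models`` to recover the assignment from must be supplied.
    """
    if responses.n_runs == 0:
        raise ValueError("empty response table")
    if design is None and reference_models is None:
        raise ValueError("need a design or reference models to locate the runs")
    logger.info("config %s: %d runs, %d responses, FOP->%g",
                config.digest(), responses.n_runs, len(responses.columns),
                config.fop_encoding)

    if design is None:
        assignment = doe.infer_run_assignment(
            responses, reference_models, n_center=config.n_center
        )
        design = doe.design_from_assignment(assignment, config.factors)
        logger.info("recovered run assignment for %d runs", len(assignment))
    if design.n_runs != responses.n_runs:
        raise ValueError(
            f"design has {design.n_runs} runs but table has {responses.n_runs}"
        )

    enc = responses.encoded(config.fop_encoding)
    models = [
        rsm.fit_full_quadratic(design, enc[c].to_numpy(), response_name=c)
        for c in enc.columns
    ]
    reduced = [
        rsm.reduce_model(m, design, enc[m.response_name].to_numpy(), alpha=config.alpha)
        for m in models
    ]

    goals = config.goals
    if goals is None:
        if config.anchor_mode == "threshold":
            goals = des.threshold_goals(responses.columns, table=responses)
        else:
            goals = des.observed_range_goals(responses.columns, responses)
    for g in goals:
        logger.info("goal %s: %s over [%g, %g], impact %d",
                    g.response_name, g.direction, g.low, g.high, g.impact)

    opt_models = reduced if config.use_reduced_models else models
    mro = des.optimize(opt_models, goals, grid_n=config.grid_n, factors=config.factors)

    classification = {
        m.response_name: classify_separation(max(0.0, m.predict(mro.coded_optimum)))
        for m in models
        if m.response_name.startswith("Rs")
    }
    return {
        "config_hash": config.digest(),
        "design": design,
        "models": models,
        "reduced_models": reduced,
        "significant": {
            m.response_name: m.significant_terms(config.alpha) for m in models
        },
        "goals": goals,
        "mro": mro,
        "classification": classification,
    }


def report_text(report: dict) -> str:
    """Render the report bundle as a deterministic plain-text summary."""
    lines = [f"config: {report['config_hash']}", "", "fitted models (coded scale):"]
    frame = rsm.models_to_frame(report["models"])
    lines.append(frame.round(4).to_string())
    lines.append("")
    lines.append("significant terms (p < alpha):")
    for name, terms in report["significant"].items():
        lines.append(f"  {name}: {', '.join(terms) if terms else '-'}")
    mro = report["mro"]
    lines.append("")
    lines.append(f"composite desirability D = {mro.composite_D:.4f}")
    lines.append(f"coded optimum:   ({', '.join(f'{v:.3f}' for v in mro.coded_optimum)})")
    if mro.uncoded_optimum is not None:
        lines.append(
            f"uncoded optimum: ({', '.join(f'{v:.2f}' for v in mro.uncoded_optimum)})"
        )
    lines.append("")
    lines.append("predicted separation at the optimum:")
    for name, d in mro.per_response.items():
        cls = report["classification"].get(name, "")
        lines.append(
            f"  {name}: {d['predicted']:.3f} (d={d['d']:.3f})"
            + (f" -> {cls}" if cls else "")
        )
    return "\n".join(lines) + "\n"
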