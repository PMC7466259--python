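"""Readers and writers for designs, models, goals and configs.

Everything is plain text: comma-separated tables with a header row
("FOP" is the only non-numeric response token), JSON for model
coefficient bundles, YAML for goal and analyte configurations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .desirability import DesirabilityGoal
from .doe import Design, DesignPoint, FactorSpec
from .rsm import TERM_NAMES, QuadraticModel
from .simulate import AnalyteSim

__all__ = [
    "write_design",
    "read_design",
    "write_models",
    "read_models",
    "read_goals",
    "write_goals",
    "read_analytes",
    "write_analytes",
]


def write_design(design: Design, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(path, factors: list[FactorSpec] | None = None) -> Design:
    """Read a design table. Factor names/units are reconstructed from the
    header when ``factors`` is not given, with levels from the coded span."""
    df = pd.read_csv(path)
    coded_cols = [c for c in df.columns if c.endswith("_coded")]
    k = len(coded_cols)
    if factors is None:
        unc_cols = [
            c for c in df.columns if c not in coded_cols + ["run", "is_center"]
        ]
        factors = []
        for cc, uc in zip(coded_cols, unc_cols):
            x, u = df[cc].to_numpy(dtype=float), df[uc].to_numpy(dtype=float)
            span = x.max() - x.min()
            half = (u.max() - u.min()) / span if span else 1.0
            center = float(np.mean(u - x * half))
            factors.append(FactorSpec(uc, center - half, center + half))
    points = [
        DesignPoint(run_id=int(r["run"]), coded=tuple(float(r[c]) for c in coded_cols))
        for _, r in df.iterrows()
    ]
    n_center = sum(p.is_center for p in points)
    return Design(factors=factors, points=points, n_center=n_center)


def _model_to_dict(m: QuadraticModel) -> dict:
    d = {
        "response_name": m.response_name,
        "terms": list(m.terms),
        "coef": [float(v) for v in m.coef],
    }
    for fld in ("r2", "r2_adj", "se", "mae", "n_obs", "df_resid"):
        v = getattr(m, fld)
        if v is not None:
            d[fld] = float(v) if fld not in ("n_obs", "df_resid") else int(v)
    if m.p_values is not None:
        d["p_values"] = [float(v) for v in m.p_values]
    return d


def write_models(models: list[QuadraticModel], path) -> None:
    Path(path).write_text(
        json.dumps({"models": [_model_to_dict(m) for m in models]}, indent=1)
    )


def read_models(path) -> list[QuadraticModel]:
    data = json.loads(Path(path).read_text())
    out = []
    for d in data["models"]:
        out.append(
            QuadraticModel(
                response_name=d["response_name"],
                coef=np.array(d["coef"]),
                terms=tuple(d.get("terms", TERM_NAMES)),
                p_values=np.array(d["p_values"]) if "p_values" in d else None,
                r2=d.get("r2"),
                r2_adj=d.get("r2_adj"),
                se=d.get("se"),
                mae=d.get("mae"),
                n_obs=d.get("n_obs"),
                df_resid=d.get("df_resid"),
            )
        )
    return out


def write_goals(goals: list[DesirabilityGoal], path) -> None:
    data = [
        {
            "response": g.response_name,
            "direction": g.direction,
            "low": g.low,
            "high": g.high,
            **({"target": g.target} if g.target is not None else {}),
            "shape": g.shape,
            "impact": g.impact,
        }
        for g in goals
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_goals(path) -> list[DesirabilityGoal]:
    data = yaml.safe_load(Path(path).read_text())
    return [
        DesirabilityGoal(
            response_name=d["response"],
            direction=d["direction"],
            low=float(d["low"]),
            high=float(d["high"]),
            target=float(d["target"]) if "target" in d else None,
            shape=float(d.get("shape", 1.0)),
            impact=int(d.get("impact", 3)),
        )
        for d in data
    ]


def write_analytes(analytes: list[AnalyteSim], path) -> None:
    data = [
        {
            "name": a.name,
            "log_kw_neutral": a.log_kw_neutral,
            "S": a.S,
            **({"pKa": a.pKa, "log_kw_ionized": a.log_kw_ionized} if a.pKa is not None else {}),
            "acid": a.acid,
            "plate_count": a.plate_count,
        }
        for a in analytes
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_analytes(path) -> list[AnalyteSim]:
    data = yaml.safe_load(Path(path).read_text())
    return [
        AnalyteSim(
            name=d["name"],
            log_kw_neutral=float(d["log_kw_neutral"]),
            S=float(d["S"]),
            pKa=float(d["pKa"]) if d.get("pKa") is not None else None,
            log_kw_ionized=(
                float(d["log_kw_ionized"]) if d.get("log_kw_ionized") is not None else None
            ),
            acid=bool(d.get("acid", True)),
            plate_count=float(d.get("plate_count", 10000.0)),
        )
        for d in data
    ]
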