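"""Derringer-Suich desirability transforms and multi-response optimization.

Each response y is mapped to an individual desirability d(y) in [0, 1]
through a piecewise power ramp, and responses are combined as the
importance-weighted geometric mean

    D = (prod_i d_i^w_i)^(1 / sum_i w_i)

with integer impact coefficients w_i in 1..5. D is 0 as soon as any single
response is fully undesirable, which is what makes the composite suitable
for separation problems: one fully overlapped pair vetoes the condition.

The optimizer evaluates D over a uniform lattice on the coded factor cube
[-1, 1]^3 and polishes the best cell with a Nelder-Mead local search,
deterministically.

Anchor choice matters. For resolution responses the default goals ramp
from Rs = 0 (co-elution, d = 0) to Rs = 1.5 (complete baseline
separation, d = 1): beyond 1.5 extra resolution buys nothing analytically,
so desirability saturates. The alternative of anchoring at each response's
observed extremes is provided (``observed_range_goals``) but tends to
reward pushing already-huge resolutions higher and can drag the optimum to
the boundary of the factor cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .rsm import QuadraticModel, design_matrix

__all__ = [
    "DesirabilityGoal",
    "MROResult",
    "d_individual",
    "composite",
    "optimize",
    "threshold_goals",
    "observed_range_goals",
    "RS_FULL_SEPARATION",
]

#: Resolution at (and above) which two peaks are completely separated.
RS_FULL_SEPARATION = 1.5


@dataclass(frozen=True)
class DesirabilityGoal:
    """Target definition for one response."""

    response_name: str
    direction: str  # maximize | minimize | target
    low: float
    high: float
    target: float | None = None
    shape: float = 1.0
    impact: int = 3

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize", "target"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.low < self.high:
            raise ValueError(
                f"{self.response_name}: low ({self.low}) must be < high ({self.high})"
            )
        if self.shape <= 0:
            raise ValueError("shape exponent must be positive")
        if not 1 <= self.impact <= 5:
            raise ValueError("impact coefficient must be in 1..5")
        if self.direction == "target":
            if self.target is None or not self.low < self.target < self.high:
                raise ValueError("target must lie strictly inside (low, high)")


@dataclass
class MROResult:
    """Outcome of a multi-response optimization over the coded cube."""

    coded_optimum: tuple[float, float, float]
    uncoded_optimum: tuple[float, ...] | None
    composite_D: float
    per_response: dict[str, dict[str, float]]
    all_zero: bool = False


def d_individual(y: float, goal: DesirabilityGoal) -> float:
    """Individual desirability of a response value under a goal."""
    lo, hi, s = goal.low, goal.high, goal.shape
    if goal.direction == "maximize":
        if y <= lo:
            return 0.0
        if y >= hi:
            return 1.0
        return float(((y - lo) / (hi - lo)) ** s)
    if goal.direction == "minimize":
        if y >= hi:
            return 0.0
        if y <= lo:
            return 1.0
        return float(((hi - y) / (hi - lo)) ** s)
    # two-sided ramp peaking at the target
    t = goal.target
    if y <= lo or y >= hi:
        return 0.0
    if y <= t:
        return float(((y - lo) / (t - lo)) ** s)
    return float(((hi - y) / (hi - t)) ** s)


def composite(d_values, impacts) -> float:
    """Impact-weighted geometric mean of individual desirabilities."""
    d = np.asarray(d_values, dtype=float)
    w = np.asarray(impacts, dtype=float)
    if d.size == 0:
        raise ValueError("no desirabilities to combine")
    if d.shape != w.shape:
        raise ValueError("d_values and impacts lengths differ")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("desirabilities must lie in [0, 1]")
    if np.any(d == 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / np.sum(w)))


def threshold_goals(
    response_names,
    table=None,
    rs_impact: int = 3,
    time_impact: int = 1,
    time_range: tuple[float, float] | None = None,
) -> list[DesirabilityGoal]:
    """Default goal set for a separation study.

    Resolution columns (names starting ``Rs``) are maximized on a ramp from
    0 (fully overlapped) to :data:`RS_FULL_SEPARATION`; the analysis-time
    column is minimized over its observed range (or an explicit
    ``time_range``).
    """
    goals = []
    for name in response_names:
        if name.startswith("Rs"):
            goals.append(
                DesirabilityGoal(name, "maximize", 0.0, RS_FULL_SEPARATION, impact=rs_impact)
            )
        else:
            if time_range is not None:
                lo, hi = time_range
            elif table is not None:
                col = table.column(name)
                lo, hi = float(np.min(col)), float(np.max(col))
            else:
                raise ValueError(
                    f"need a response table or explicit range for {name!r}"
                )
            goals.append(DesirabilityGoal(name, "minimize", lo, hi, impact=time_impact))
    return goals


def observed_range_goals(
    response_names, table, rs_impact: int = 3, time_impact: int = 1
) -> list[DesirabilityGoal]:
    """Alternative goal set anchoring every response at its observed min/max."""
    goals = []
    for name in response_names:
        col = table.column(name)
        lo, hi = float(np.min(col)), float(np.max(col))
        if name.startswith("Rs"):
            goals.append(DesirabilityGoal(name, "maximize", lo, hi, impact=rs_impact))
        else:
            goals.append(DesirabilityGoal(name, "minimize", lo, hi, impact=time_impact))
    return goals


def _d_matrix(Y: np.ndarray, goals) -> np.ndarray:
    """Vectorized individual desirabilities, points x responses."""
    D = np.empty_like(Y)
    for j, g in enumerate(goals):
        y = Y[:, j]
        if g.direction == "maximize":
            D[:, j] = np.clip((y - g.low) / (g.high - g.low), 0.0, 1.0) ** g.shape
        elif g.direction == "minimize":
            D[:, j] = np.clip((g.high - y) / (g.high - g.low), 0.0, 1.0) ** g.shape
        else:
            up = np.clip((y - g.low) / (g.target - g.low), 0.0, 1.0)
            dn = np.clip((g.high - y) / (g.high - g.target), 0.0, 1.0)
            D[:, j] = np.minimum(up, dn) ** g.shape
    return D


def _composite_vec(Dind: np.ndarray, w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logs = np.where(Dind > 0, np.log(np.maximum(Dind, 1e-300)), -np.inf)
        logD = (w * logs).sum(axis=1) / w.sum()
    out = np.exp(logD)
    out[~np.isfinite(logD)] = 0.0
    return out


def optimize(
    models: list[QuadraticModel],
    goals: list[DesirabilityGoal],
    grid_n: int = 201,
    factors=None,
    polish: bool = True,
) -> MROResult:
    """Maximize the composite desirability of several fitted models.

    A full ``grid_n``^3 lattice over the coded cube is scanned (chunked by
    the first coordinate to bound memory), then the best cell is refined
    with Nelder-Mead clipped to the cube. Deterministic; exact grid ties
    resolve to the lexicographically smallest coded point because the scan
    is in lexicographic order and only strict improvements are kept.
    """
    if len(models) != len(goals):
        raise ValueError("one goal per model required")
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    by_name = {m.response_name for m in models}
    for g in goals:
        if g.response_name not in by_name:
            raise ValueError(f"goal {g.response_name!r} matches no model")
    order = {m.response_name: i for i, m in enumerate(models)}
    goals = sorted(goals, key=lambda g: order[g.response_name])

    B = np.stack([m.coef_full() for m in models], axis=1)  # 10 x r
    w = np.array([g.impact for g in goals], dtype=float)
    axis = np.linspace(-1.0, 1.0, grid_n)

    best_D = -1.0
    best_p = np.array([-1.0, -1.0, -1.0])
    g2, g3 = np.meshgrid(axis, axis, indexing="ij")
    flat2, flat3 = g2.ravel(), g3.ravel()
    for a in axis:
        P = np.column_stack([np.full(flat2.size, a), flat2, flat3])
        Y = design_matrix(P) @ B
        Dc = _composite_vec(_d_matrix(Y, goals), w)
        i = int(np.argmax(Dc))  # argmax returns the first (lexicographically
        # smallest) maximizer within the slice
        if Dc[i] > best_D:
            best_D = float(Dc[i])
            best_p = P[i]

    def neg_D(p):
        q = np.clip(p, -1.0, 1.0)
        Y = design_matrix(q[None, :]) @ B
        return -_composite_vec(_d_matrix(Y, goals), w)[0]

    opt = best_p
    if polish and best_D > 0:
        res = minimize(
            neg_D,
            best_p,
            method="Nelder-Mead",
            options=dict(xatol=1e-9, fatol=1e-13, maxiter=5000),
        )
        cand = np.clip(res.x, -1.0, 1.0)
        if -res.fun > best_D:  # strict: a flat surface keeps the grid point
            opt, best_D = cand, float(-res.fun)

    all_zero = best_D <= 0.0
    Yopt = design_matrix(opt[None, :]) @ B
    dind = _d_matrix(Yopt, goals)[0]
    per = {
        g.response_name: {"predicted": float(Yopt[0, j]), "d": float(dind[j])}
        for j, g in enumerate(goals)
    }
    uncoded = None
    if factors is not None:
        from .doe import uncode

        uncoded = uncode(tuple(opt), factors)
    return MROResult(
        coded_optimum=tuple(float(v) for v in opt),
        uncoded_optimum=uncoded,
        composite_D=max(best_D, 0.0),
        per_response=per,
        all_zero=all_zero,
    )
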