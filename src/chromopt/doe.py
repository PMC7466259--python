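"""Three-level Box-Behnken designs with coded/uncoded factor handling.

A Box-Behnken design (BBD) for k factors places runs at the midpoints of
the edges of the factor cube (exactly two coordinates at +/-1, the rest at
0) plus replicated center points. For k = 3 this gives 12 edge runs; with
the customary three center replicates the design has 15 runs, enough to
estimate all ten coefficients of a full second-order polynomial while
providing a pure-error estimate from the replicates.

Factors are handled on two scales. The *coded* scale maps each factor's
low/center/high levels to -1/0/+1, on which designs are constructed and
models fitted; :func:`uncode` and :func:`code` translate between the coded
scale and the native units (percent organic modifier, pH, ...).

The module also provides :func:`infer_run_assignment`, which recovers a
lost run-to-factor-combination mapping from a response table and a set of
previously fitted quadratic models by solving a linear assignment problem.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "FactorSpec",
    "DesignPoint",
    "Design",
    "build_bbd",
    "code",
    "uncode",
    "find_center_runs",
    "infer_run_assignment",
    "InvalidDesignError",
]


class InvalidDesignError(ValueError):
    """Raised when a design cannot be constructed or is internally inconsistent."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental variable with its uncoded low/high levels.

    Coded -1 maps to ``low``, +1 to ``high`` and 0 to the midpoint.
    """

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise InvalidDesignError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


@dataclass(frozen=True)
class DesignPoint:
    """A single run: its identifier and coded factor settings."""

    run_id: int
    coded: tuple[float, ...]

    @property
    def is_center(self) -> bool:
        return all(c == 0 for c in self.coded)


@dataclass
class Design:
    """A Box-Behnken design: factors, runs and the center-replicate count."""

    factors: list[FactorSpec]
    points: list[DesignPoint]
    n_center: int
    seed: int | None = None

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.points)

    def coded_matrix(self) -> np.ndarray:
        """Runs x factors array of coded settings, in run order."""
        return np.array([p.coded for p in self.points], dtype=float)

    def uncoded_matrix(self) -> np.ndarray:
        return np.array([uncode(p.coded, self.factors) for p in self.points])

    def to_frame(self):
        """Design as a DataFrame with coded and uncoded columns."""
        import pandas as pd

        coded = self.coded_matrix()
        unc = self.uncoded_matrix()
        data: dict = {"run": [p.run_id for p in self.points]}
        for j, f in enumerate(self.factors):
            data[f"x{j + 1}_coded"] = coded[:, j]
        for j, f in enumerate(self.factors):
            data[f.name] = unc[:, j]
        data["is_center"] = [p.is_center for p in self.points]
        return pd.DataFrame(data)


def _bbd_edge_combinations(k: int) -> list[tuple[float, ...]]:
    """Canonical BBD edge set: for each factor pair, the four +/-1 corners.

    Pairs in lexicographic order (x1,x2), (x1,x3), ..., each in
    (-,-), (-,+), (+,-), (+,+) order.
    """
    combos: list[tuple[float, ...]] = []
    for i, j in itertools.combinations(range(k), 2):
        for a, b in [(-1.0, -1.0), (-1.0, 1.0), (1.0, -1.0), (1.0, 1.0)]:
            point = [0.0] * k
            point[i], point[j] = a, b
            combos.append(tuple(point))
    return combos


def build_bbd(
    factors: list[FactorSpec],
    n_center: int = 3,
    seed: int | None = None,
    randomize: bool = False,
) -> Design:
    """Construct a Box-Behnken design.

    Parameters
    ----------
    factors:
        At least three :class:`FactorSpec`. Three factors give the classic
        12-edge-run design.
    n_center:
        Number of replicated center points appended after the edge runs.
    seed:
        Seed for run-order randomization. Stored on the design either way;
        the canonical (unrandomized) order is used unless ``randomize``.
    randomize:
        If true, shuffle the run order deterministically from ``seed``.
        Run ids always label the returned order 1..n.
    """
    k = len(factors)
    if k < 3:
        raise InvalidDesignError(f"a Box-Behnken design needs >= 3 factors, got {k}")
    if n_center < 0:
        raise InvalidDesignError("n_center must be non-negative")
    combos = _bbd_edge_combinations(k)
    combos += [tuple([0.0] * k)] * n_center
    if randomize:
        rng = np.random.default_rng(seed)
        combos = [combos[i] for i in rng.permutation(len(combos))]
    points = [DesignPoint(run_id=i + 1, coded=c) for i, c in enumerate(combos)]
    return Design(factors=list(factors), points=points, n_center=n_center, seed=seed)


def uncode(coded, factors: list[FactorSpec]) -> tuple[float, ...]:
    """Map coded coordinates to native factor units.

    ``uncoded_i = center_i + coded_i * half_range_i``.
    """
    if isinstance(coded, DesignPoint):
        coded = coded.coded
    if len(coded) != len(factors):
        raise InvalidDesignError("coded point and factor list lengths differ")
    return tuple(f.center + c * f.half_range for c, f in zip(coded, factors))


def code(uncoded, factors: list[FactorSpec]) -> tuple[float, ...]:
    """Inverse of :func:`uncode`: native units back to the coded scale."""
    if len(uncoded) != len(factors):
        raise InvalidDesignError("uncoded point and factor list lengths differ")
    return tuple((u - f.center) / f.half_range for u, f in zip(uncoded, factors))


def find_center_runs(responses: np.ndarray, n_center: int = 3) -> tuple[int, ...]:
    """Identify the replicated center runs in a response matrix.

    Center replicates are the ``n_center`` rows that cluster most tightly:
    the subset minimizing the summed pairwise squared distance after
    range-normalizing each response column. Returns 0-based row indices,
    sorted. Exhaustive over subsets, fine for the 15-run designs this
    package targets.
    """
    y = np.asarray(responses, dtype=float)
    y = np.nan_to_num(y, nan=0.0)
    rng = y.max(axis=0) - y.min(axis=0)
    z = y / np.where(rng > 0, rng, 1.0)
    best: tuple[float, tuple[int, ...]] | None = None
    for subset in itertools.combinations(range(len(y)), n_center):
        d = sum(
            float(np.sum((z[a] - z[b]) ** 2))
            for a, b in itertools.combinations(subset, 2)
        )
        if best is None or d < best[0]:
            best = (d, subset)
    assert best is not None
    return best[1]


def infer_run_assignment(
    responses,
    printed_models,
    factors: list[FactorSpec] | None = None,
    center_runs: tuple[int, ...] | None = None,
    n_center: int = 3,
    recenter: bool = True,
) -> dict[int, DesignPoint]:
    """Recover which factor combination each run used, from fitted models.

    When a response table lists runs without their factor settings, the
    mapping can be reconstructed provided quadratic models fitted to the
    original data are available: each non-center run is matched to the BBD
    edge combination whose model predictions best explain its responses,
    through a minimum-cost linear assignment (Hungarian algorithm) with

        cost(run r, combo c) = sum over responses (y_r - yhat(c))^2.

    Parameters
    ----------
    responses:
        Response matrix (runs x responses) or :class:`~chromopt.peaks.ResponseTable`;
        overlapped-peak cells are encoded as 0 first.
    printed_models:
        One fitted :class:`~chromopt.rsm.QuadraticModel` per response column,
        in column order.
    center_runs:
        0-based indices of the center replicates. Detected with
        :func:`find_center_runs` when omitted.
    recenter:
        Replace each model's intercept with the mean of the center-run
        responses before computing costs. On a coded BBD the least-squares
        intercept *is* the center mean, so this guards against a reported
        intercept that is inconsistent with the replicates.

    Returns
    -------
    dict mapping 1-based run_id to :class:`DesignPoint` (center runs map to
    the all-zero point).
    """
    from .peaks import ResponseTable
    from .rsm import QuadraticModel  # noqa: F401  (type reference)

    if isinstance(responses, ResponseTable):
        y = responses.encoded().to_numpy(dtype=float)
    else:
        y = np.asarray(responses, dtype=float)
    n_runs, n_resp = y.shape
    if len(printed_models) != n_resp:
        raise ValueError(
            f"{n_resp} response columns but {len(printed_models)} models"
        )
    if center_runs is None:
        center_runs = find_center_runs(y, n_center=n_center)
    center_runs = tuple(sorted(center_runs))
    noncenter = [i for i in range(n_runs) if i not in center_runs]
    combos = _bbd_edge_combinations(3)
    if len(noncenter) != len(combos):
        raise ValueError(
            f"assignment is not square: {len(noncenter)} non-center runs "
            f"vs {len(combos)} edge combinations"
        )

    center_mean = y[list(center_runs)].mean(axis=0)
    pred = np.empty((len(combos), n_resp))
    for jc, cpt in enumerate(combos):
        for jm, m in enumerate(printed_models):
            val = m.predict(cpt)
            if recenter:
                val = val - m.beta0 + center_mean[jm]
            pred[jc, jm] = val

    cost = ((y[noncenter][:, None, :] - pred[None, :, :]) ** 2).sum(axis=2)
    # deterministic tie-break: nudge costs so earlier runs prefer
    # lexicographically smaller combos when exactly tied
    eps = 1e-12 * (1.0 + np.abs(cost).max())
    tie = np.arange(len(noncenter))[:, None] * np.arange(len(combos))[None, :]
    rows, cols = linear_sum_assignment(cost + eps * tie)

    mapping: dict[int, DesignPoint] = {}
    for r, c in zip(rows, cols):
        run = noncenter[r]
        mapping[run + 1] = DesignPoint(run_id=run + 1, coded=combos[c])
    for r in center_runs:
        mapping[r + 1] = DesignPoint(run_id=r + 1, coded=(0.0, 0.0, 0.0))
    return dict(sorted(mapping.items()))


def design_from_assignment(
    assignment: dict[int, DesignPoint],
    factors: list[FactorSpec],
    n_center: int | None = None,
) -> Design:
    """Build a :class:`Design` from a run_id -> point mapping, in run order."""
    points = [assignment[r] for r in sorted(assignment)]
    if n_center is None:
        n_center = sum(p.is_center for p in points)
    return Design(factors=list(factors), points=points, n_center=n_center)
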