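"""Method-validation metrics: linearity, LOD/LOQ, recovery, precision,
and regulatory compliance checks.

Follows the ICH Q2(R1) conventions: detection and quantification limits
from the calibration line as 3.3 sigma / S and 10 sigma / S, with sigma
the residual standard error and S the slope; spike recovery accepted in
the 80-110% window; replicate precision as percent coefficient of
variation with a 2% gate for system-suitability injections and the AOAC
10% gate for intraday/interday precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "CalibrationFit",
    "PrecisionReport",
    "calibrate",
    "recovery",
    "precision",
    "check_compliance",
    "RECOVERY_WINDOW",
    "SST_CV_LIMIT",
    "AOAC_CV_LIMIT",
]

RECOVERY_WINDOW = (80.0, 110.0)
SST_CV_LIMIT = 2.0  # percent, replicate-injection suitability gate
AOAC_CV_LIMIT = 10.0  # percent, intraday/interday acceptance


@dataclass(frozen=True)
class CalibrationFit:
    """Linear calibration y = slope * x + intercept with ICH limits."""

    slope: float
    intercept: float
    r2: float
    se_residual: float
    lod: float
    loq: float
    n: int


@dataclass(frozen=True)
class PrecisionReport:
    mode: str
    cv: float  # percent
    n: int
    passes_sst: bool
    passes_aoac: bool


def calibrate(concentrations, signals) -> CalibrationFit:
    """Least-squares calibration line and detection/quantification limits.

    lod = 3.3 * se_residual / slope, loq = 10 * se_residual / slope, so
    loq / lod = 10 / 3.3 for every fit with nonzero residual.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.size != y.size:
        raise ValueError("concentration and signal lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    intercept, slope = res.params
    scale = max(1.0, float(np.abs(y).max())) / max(1.0, float(np.abs(x).max()))
    if abs(slope) <= 1e-12 * scale:
        raise ZeroDivisionError("zero calibration slope: limits undefined")
    resid = y - res.fittedvalues
    se = float(np.sqrt((resid @ resid) / (x.size - 2)))
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - float(resid @ resid) / sst
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        r2=r2,
        se_residual=se,
        lod=3.3 * se / abs(float(slope)),
        loq=10.0 * se / abs(float(slope)),
        n=int(x.size),
    )


def recovery(measured: float, baseline: float, spiked: float) -> tuple[float, bool]:
    """Spike recovery percentage and whether it falls in the 80-110% window."""
    if spiked <= 0:
        raise ValueError("spiked amount must be positive")
    pct = 100.0 * (measured - baseline) / spiked
    lo, hi = RECOVERY_WINDOW
    return pct, lo <= pct <= hi


def precision(values, mode: str = "sst") -> PrecisionReport:
    """Replicate precision as percent CV (sample standard deviation).

    ``mode`` is one of ``sst`` (suitability gate, CV < 2%), ``intraday`` or
    ``interday`` (AOAC gate, CV <= 10%); the report carries both verdicts.
    """
    if mode not in ("sst", "intraday", "interday"):
        raise ValueError(f"unknown precision mode {mode!r}")
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(v.mean())
    if mean == 0:
        raise ZeroDivisionError("zero mean: CV undefined")
    cv = 100.0 * float(v.std(ddof=1)) / abs(mean)
    return PrecisionReport(
        mode=mode,
        cv=cv,
        n=int(v.size),
        passes_sst=cv < SST_CV_LIMIT,
        passes_aoac=cv <= AOAC_CV_LIMIT,
    )


def check_compliance(
    analyte: str, concentration: float, limits: dict[str, float] | None = None
) -> str:
    """Judge a measured concentration against the regulatory maximum.

    Returns ``"compliant"`` (inclusive at the limit) or ``"exceeds"``.
    """
    from .fixtures import NADFC_LIMITS

    table = NADFC_LIMITS if limits is None else limits
    if analyte not in table:
        raise KeyError(
            f"no regulatory limit for {analyte!r}; known: {sorted(table)}"
        )
    return "compliant" if concentration <= table[analyte] else "exceeds"
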