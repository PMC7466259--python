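"""Phenomenological gradient-elution chromatography simulator.

Stands in for the HPLC instrument so the whole design -> fit -> optimize
pipeline can be exercised end-to-end with known ground truth. The model is
deliberately simple but captures the three behaviors the real separation
problem turns on:

* **Solvent strength.** Retention follows the linear-solvent-strength
  (LSS) rule, log10 k = log10 kw - S * phi, with phi the organic fraction
  of the mobile phase and S the solvent-strength slope.
* **Ionization.** For ionizable analytes the aqueous retention factor kw
  is the Henderson-Hasselbalch-weighted mix of the neutral and ionized
  species: at pH = pKa the mix is 50/50, and the ionized form of an acid
  is less retained, so raising the pH of the buffer pulls acids forward.
  Analytes with ``pKa = None`` (e.g. caffeine) ignore pH.
* **Band broadening.** Peaks are Gaussian with base width 4 sigma =
  4 t_R / sqrt(N) from a constant plate count N.

Retention times under a linear gradient solve

    integral_0^(tR - t0) dt / (t0 * k(phi(t))) = 1

with phi(t) ramping linearly from ``phi_initial`` to ``phi_end`` over
``duration`` and held at ``phi_end`` afterwards. Because log k is linear
in t along the ramp, the integral has an exact piecewise closed form,
which is what :func:`retention_time` evaluates; the isocratic limit
tR = t0 (1 + k) falls out when the ramp is flat.

The default eight-analyte set mimics a mix of sweeteners, preservatives,
colorants and caffeine: mostly weak acids with pKa spread across the
pH 3-7 working window (so pH effects on the response surfaces are strong),
plus two pH-insensitive analytes. It is a synthetic parameter set chosen
for realistic retention behavior, not a calibration to any instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .doe import Design, uncode
from .peaks import Chromatogram, Peak, ResponseTable, response_row

__all__ = [
    "AnalyteSim",
    "GradientProgram",
    "retention_factor",
    "retention_time",
    "simulate_run",
    "generate_study",
    "default_analytes",
    "NotElutedError",
]

LN10 = math.log(10.0)


class NotElutedError(RuntimeError):
    """An analyte failed to elute within the gradient plus hold window."""


@dataclass(frozen=True)
class AnalyteSim:
    """Ground-truth simulator parameters for one analyte."""

    name: str
    log_kw_neutral: float
    S: float
    pKa: float | None = None
    log_kw_ionized: float | None = None
    acid: bool = True
    plate_count: float = 10000.0
    area: float = 1.0

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError(f"{self.name}: solvent-strength slope S must be > 0")
        if self.plate_count <= 0:
            raise ValueError(f"{self.name}: plate count must be > 0")
        if self.pKa is not None:
            if self.log_kw_ionized is None:
                raise ValueError(f"{self.name}: ionizable analyte needs log_kw_ionized")
            if self.acid and self.log_kw_ionized > self.log_kw_neutral:
                raise ValueError(
                    f"{self.name}: ionized acid must not be more retained than neutral"
                )


@dataclass(frozen=True)
class GradientProgram:
    """Linear organic-modifier ramp, then hold at the final composition."""

    phi_initial: float
    phi_end: float
    duration: float = 30.0
    t0: float = 1.5
    hold: float = 12.0

    def __post_init__(self) -> None:
        if not 0 <= self.phi_initial <= self.phi_end <= 1:
            raise ValueError("need 0 <= phi_initial <= phi_end <= 1")
        if self.duration <= 0 or self.t0 <= 0 or self.hold < 0:
            raise ValueError("duration and t0 must be positive, hold non-negative")

    def phi_at(self, t: float) -> float:
        if t >= self.duration:
            return self.phi_end
        return self.phi_initial + (self.phi_end - self.phi_initial) * t / self.duration


def ionized_fraction(pKa: float, pH: float, acid: bool = True) -> float:
    """Henderson-Hasselbalch fraction of the ionized species."""
    if acid:
        return 1.0 / (1.0 + 10.0 ** (pKa - pH))
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def retention_factor(analyte: AnalyteSim, phi: float, pH: float) -> float:
    """Retention factor k at organic fraction ``phi`` and buffer ``pH``.

    The aqueous retention kw is the ionization-weighted mix of the neutral
    and ionized species' kw; LSS then gives k = kw * 10^(-S phi).
    """
    if not 0 <= phi <= 1:
        raise ValueError("phi must lie in [0, 1]")
    kw_n = 10.0 ** analyte.log_kw_neutral
    if analyte.pKa is None:
        kw = kw_n
    else:
        f = ionized_fraction(analyte.pKa, pH, analyte.acid)
        kw = (1.0 - f) * kw_n + f * 10.0 ** analyte.log_kw_ionized
    return kw * 10.0 ** (-analyte.S * phi)


def retention_time(
    analyte: AnalyteSim, gradient: GradientProgram, pH: float
) -> float:
    """Retention time under the gradient, from the exact LSS integral.

    Along the ramp k(t) = k0 * 10^(-b t) with b = S (phi_end - phi_initial)
    / duration, so the migration integral has the closed form used here;
    any remaining migration after the ramp is isocratic at ``phi_end``.
    Raises :class:`NotElutedError` if elution would occur after
    ``duration + hold``.
    """
    t0 = gradient.t0
    k0 = retention_factor(analyte, gradient.phi_initial, pH)
    b = analyte.S * (gradient.phi_end - gradient.phi_initial) / gradient.duration
    if b <= 0:  # flat ramp: isocratic
        tau = t0 * k0
    else:
        # fraction of migration completed by the end of the ramp
        arg_end = (10.0 ** (b * gradient.duration) - 1.0) / (t0 * k0 * b * LN10)
        if arg_end >= 1.0:
            tau = math.log1p(t0 * k0 * b * LN10) / (b * LN10)
        else:
            k_end = retention_factor(analyte, gradient.phi_end, pH)
            tau = gradient.duration + (1.0 - arg_end) * t0 * k_end
    tR = t0 + tau
    if tR > gradient.t0 + gradient.duration + gradient.hold:
        raise NotElutedError(
            f"{analyte.name} would elute at {tR:.2f} min, beyond the "
            f"{gradient.duration + gradient.hold:.1f} min window"
        )
    return tR


def simulate_run(
    analytes: list[AnalyteSim],
    gradient: GradientProgram,
    pH: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    run_id: int = 0,
) -> Chromatogram:
    """Simulate one injection: a chromatogram for all analytes.

    Optional Gaussian jitter of ``noise_sd`` minutes is added to each
    retention time (clipped so peaks stay after the dead time), seeded for
    reproducibility. Base widths are 4 tR / sqrt(N).
    """
    if not analytes:
        raise ValueError("no analytes to simulate")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    peaks = []
    for a in analytes:
        tr = retention_time(a, gradient, pH)
        if noise_sd > 0:
            tr = max(gradient.t0, tr + float(rng.normal(0.0, noise_sd)))
        w = 4.0 * tr / math.sqrt(a.plate_count)
        height = a.area / (w / 4.0 * math.sqrt(2.0 * math.pi))
        peaks.append(Peak(analyte=a.name, t=tr, w=w, area=a.area, height=height))
    meta = {
        "phi_initial": gradient.phi_initial,
        "phi_end": gradient.phi_end,
        "pH": pH,
        "noise_sd": noise_sd,
    }
    return Chromatogram(peaks=peaks, run_id=run_id, metadata=meta)


def default_analytes() -> list[AnalyteSim]:
    """Synthetic eight-analyte set spanning the pH 3-7 window.

    Mostly weak acids whose pKa values sit inside the working window, so
    ionization-driven retention shifts (and hence pH terms and pH^2
    curvature in the fitted surfaces) are strong; two analytes are
    pH-insensitive. Elution order at mild conditions runs from the
    early-eluting very polar sweetener to the late hydrophobic one.
    """
    return [
        AnalyteSim("A1", log_kw_neutral=1.60, S=4.5, pKa=2.5, log_kw_ionized=1.20),
        AnalyteSim("A2", log_kw_neutral=1.75, S=5.0, pKa=4.2, log_kw_ionized=0.90),
        AnalyteSim("A3", log_kw_neutral=1.90, S=5.0, pKa=4.8, log_kw_ionized=1.10),
        AnalyteSim("A4", log_kw_neutral=2.00, S=5.2, pKa=1.8, log_kw_ionized=1.75),
        AnalyteSim("A5", log_kw_neutral=2.15, S=5.5, pKa=None),
        AnalyteSim("A6", log_kw_neutral=2.30, S=5.5, pKa=None),
        AnalyteSim("A7", log_kw_neutral=2.45, S=5.8, pKa=6.1, log_kw_ionized=2.00),
        AnalyteSim("A8", log_kw_neutral=2.65, S=6.0, pKa=5.0, log_kw_ionized=2.20),
    ]


def _settings_from_point(point, factors) -> tuple[GradientProgram, float]:
    """Map an (uncoded) design point (%B initial, %B end, pH) to a run."""
    pct_init, pct_end, pH = point
    return (
        GradientProgram(phi_initial=pct_init / 100.0, phi_end=pct_end / 100.0),
        float(pH),
    )


def simulate_design_point(
    coded_point,
    factors,
    analytes: list[AnalyteSim],
    noise_sd: float = 0.0,
    seed: int | None = None,
    run_id: int = 0,
) -> Chromatogram:
    """Simulate the injection for one coded design point."""
    unc = uncode(coded_point, factors)
    gradient, pH = _settings_from_point(unc, factors)
    return simulate_run(analytes, gradient, pH, noise_sd=noise_sd, seed=seed, run_id=run_id)


def generate_study(
    design: Design,
    analytes: list[AnalyteSim] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    fop_threshold: float | None = None,
) -> ResponseTable:
    """Run the simulator at every design point and extract the responses.

    Each run gets an independent substream of ``seed`` so the table is
    reproducible run-by-run. Returns a :class:`ResponseTable` with one
    ``Rs`` column per adjacent pair and a ``time_min`` column; pairs below
    the overlap threshold carry FOP markers.
    """
    if analytes is None:
        analytes = default_analytes()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(design.n_runs)
    rows = []
    kwargs = {} if fop_threshold is None else {"fop_threshold": fop_threshold}
    for i, p in enumerate(design.points):
        run_seed = int(child[i].generate_state(1)[0] % (2**31))
        chrom = simulate_design_point(
            p.coded, design.factors, analytes, noise_sd=noise_sd,
            seed=run_seed, run_id=p.run_id,
        )
        rows.append(response_row(chrom, **kwargs))
    return ResponseTable.from_rows(rows)


def true_optimum(
    design_factors,
    analytes: list[AnalyteSim] | None = None,
    goals=None,
    grid_n: int = 21,
) -> tuple[tuple[float, float, float], float]:
    """Ground-truth optimum: dense grid search on the noise-free simulator.

    Evaluates the composite desirability of the *simulated* (not modeled)
    responses over a coded lattice and returns the best coded point and its
    D. Used as the oracle for end-to-end pipeline-recovery tests.
    """
    from .desirability import RS_FULL_SEPARATION, _composite_vec, _d_matrix, threshold_goals

    if analytes is None:
        analytes = default_analytes()
    axis = np.linspace(-1.0, 1.0, grid_n)
    points = [(a, b, c) for a in axis for b in axis for c in axis]
    rows = []
    for p in points:
        chrom = simulate_design_point(p, design_factors, analytes)
        row = response_row(chrom)
        rows.append([0.0 if v == "FOP" else float(v) for v in row.values()])
        names = list(row.keys())
    Y = np.asarray(rows)
    if goals is None:
        tmin, tmax = Y[:, -1].min(), Y[:, -1].max()
        goals = threshold_goals(names, time_range=(tmin, tmax))
    w = np.array([g.impact for g in goals], dtype=float)
    D = _composite_vec(_d_matrix(Y, goals), w)
    i = int(np.argmax(D))
    return points[i], float(D[i])
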