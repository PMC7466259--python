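"""Chromatograms as peak lists, pairwise resolution and run-time responses.

The optimization responses of a separation experiment are derived from the
chromatogram of each run: the resolution of every pair of adjacent peaks

    Rs = (t2 - t1) / (0.5 * (w1 + w2))

with t the retention times and w the baseline peak widths, and the analysis
time, taken as the retention time of the last-eluting peak. A pair of
analytes that co-elute produce a single peak; their cell carries the
``FOP`` (fully overlapped peaks) marker instead of a number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FOP",
    "Peak",
    "Chromatogram",
    "ResponseTable",
    "resolution",
    "response_row",
    "classify_separation",
    "InvalidPeakError",
]

#: Marker for a fully-overlapped (co-eluting) peak pair.
FOP = "FOP"

#: Default numeric stand-in for FOP cells when a response column is modeled.
FOP_ENCODING = 0.0

#: Pairs with Rs below this fraction count as fully overlapped.
DEFAULT_FOP_THRESHOLD = 0.2


class InvalidPeakError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    """One chromatographic peak: retention time and baseline width in minutes."""

    analyte: str
    t: float
    w: float
    area: float = 1.0
    height: float = 1.0

    def __post_init__(self) -> None:
        if self.t < 0:
            raise InvalidPeakError(f"{self.analyte}: retention time must be >= 0")
        if self.w <= 0:
            raise InvalidPeakError(f"{self.analyte}: base width must be > 0")


@dataclass
class Chromatogram:
    """A run's peaks in elution order, with the factor settings that produced it."""

    peaks: list[Peak]
    run_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.t, p.analyte))
        names = [p.analyte for p in self.peaks]
        if len(set(names)) != len(names):
            raise InvalidPeakError("duplicate analyte in chromatogram")

    def __len__(self) -> int:
        return len(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "analyte": [p.analyte for p in self.peaks],
                "t_min": [p.t for p in self.peaks],
                "w_min": [p.w for p in self.peaks],
                "area": [p.area for p in self.peaks],
                "height": [p.height for p in self.peaks],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, run_id: int = 0, metadata: dict | None = None):
        peaks = [
            Peak(
                analyte=str(r["analyte"]),
                t=float(r["t_min"]),
                w=float(r["w_min"]),
                area=float(r.get("area", 1.0)),
                height=float(r.get("height", 1.0)),
            )
            for _, r in df.iterrows()
        ]
        return cls(peaks=peaks, run_id=run_id, metadata=metadata or {})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, run_id: int = 0):
        return cls.from_frame(pd.read_csv(path), run_id=run_id)


def resolution(first: Peak, second: Peak) -> float:
    """Pairwise resolution Rs = (t2 - t1) / (0.5 (w1 + w2)).

    The caller supplies the peaks in elution order; coincident peaks give 0.
    """
    if first.w + second.w <= 0:
        raise InvalidPeakError("combined base width must be positive")
    if second.t < first.t:
        raise InvalidPeakError(
            f"peaks out of order: t1={first.t} > t2={second.t}"
        )
    return (second.t - first.t) / (0.5 * (first.w + second.w))


def classify_separation(rs: float) -> str:
    """Bin a resolution into separation quality.

    >= 1.5 is complete ("full") baseline separation; 1.0-1.5 is acceptable
    (about 98% separation); below 1.0 is poor.
    """
    if rs < 0:
        raise InvalidPeakError("resolution cannot be negative")
    if rs >= 1.5:
        return "full"
    if rs >= 1.0:
        return "acceptable"
    return "poor"


def response_row(
    chrom: Chromatogram, fop_threshold: float = DEFAULT_FOP_THRESHOLD
) -> dict[str, float | str]:
    """Extract one response-table row from a chromatogram.

    Returns ``{"Rs1-2": ..., ..., "time_min": ...}``: the resolution of each
    adjacent pair in elution order (``FOP`` when below ``fop_threshold``)
    and the analysis time, i.e. the retention time of the last peak.
    """
    if len(chrom.peaks) == 0:
        raise InvalidPeakError("empty chromatogram")
    if len(chrom.peaks) < 2:
        raise InvalidPeakError("need at least two peaks for resolution responses")
    row: dict[str, float | str] = {}
    for i, (a, b) in enumerate(zip(chrom.peaks, chrom.peaks[1:])):
        rs = resolution(a, b)
        row[f"Rs{i + 1}-{i + 2}"] = FOP if rs < fop_threshold else rs
    row["time_min"] = chrom.peaks[-1].t
    return row


class ResponseTable:
    """Run-by-response table whose resolution cells may carry FOP markers.

    Internally two aligned DataFrames: ``values`` (float, NaN at FOP cells)
    and ``fop`` (boolean mask). :meth:`encoded` substitutes a numeric value
    for the FOP cells so the table can be modeled.
    """

    def __init__(self, values: pd.DataFrame, fop: pd.DataFrame | None = None):
        self.values = values.astype(float)
        if fop is None:
            fop = pd.DataFrame(
                False, index=values.index, columns=values.columns
            )
        self.fop = fop.astype(bool)
        if not self.values.columns.equals(self.fop.columns):
            raise ValueError("values/fop column mismatch")

    # -- construction ----------------------------------------------------
    @classmethod
    def from_rows(cls, rows: list[dict[str, float | str]]) -> "ResponseTable":
        cols = list(rows[0])
        vals = pd.DataFrame(
            [[np.nan if r[c] == FOP else float(r[c]) for c in cols] for r in rows],
            columns=cols,
        )
        mask = pd.DataFrame(
            [[r[c] == FOP for c in cols] for r in rows], columns=cols
        )
        return cls(vals, mask)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseTable":
        """Parse a raw table whose cells may hold the literal string FOP."""
        mask = df.map(lambda v: isinstance(v, str) and v.strip().upper() == FOP)
        vals = df.mask(mask).apply(pd.to_numeric)
        return cls(vals, mask)

    # -- access ----------------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_runs(self) -> int:
        return len(self.values)

    def encoded(self, fop_value: float = FOP_ENCODING) -> pd.DataFrame:
        """Numeric view with FOP cells replaced by ``fop_value``."""
        return self.values.where(~self.fop, fop_value)

    def column(self, name: str, fop_value: float = FOP_ENCODING) -> np.ndarray:
        return self.encoded(fop_value)[name].to_numpy()

    def n_fop(self) -> int:
        return int(self.fop.to_numpy().sum())

    def display(self) -> pd.DataFrame:
        """Human-readable view with literal FOP strings."""
        return self.values.astype(object).where(~self.fop, FOP)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResponseTable):
            return NotImplemented
        return self.fop.equals(other.fop) and self.encoded().round(12).equals(
            other.encoded().round(12)
        )

    # -- io ----------------------------------------------------------------
    def write_csv(self, path) -> None:
        out = self.display()
        out.insert(0, "run", np.arange(1, self.n_runs + 1))
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ResponseTable":
        df = pd.read_csv(Path(path), dtype=str)
        if "run" in df.columns:
            df = df.drop(columns=["run"])
        return cls.from_frame(df)
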