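"""Bundled dataset from a published HPLC-DAD separation study.

The package ships, verbatim, the printed tables of a method-development
study that separated seven food additives and caffeine (elution order
ACE, BEN, SOR, SAC, TAR, CAF, SUN, ASP) on a C18 column with a
methanol/phosphate-buffer gradient:

* the three factor definitions and their levels (%B initial 0-10,
  %B end 60-100, buffer pH 3-7),
* the 15-run Box-Behnken response table — seven adjacent-pair resolutions
  and the analysis time, with ``FOP`` markers where a pair co-eluted,
* the study's reported second-order coefficient matrix with fit metrics,
* measured additive concentrations in nine commercial powdered-drink
  samples, and
* the Indonesian NADFC maximum-concentration limits used to judge them.

These are loaded through :func:`load_fixture` and drive the reproduction
pipeline and the acceptance checks. The three center replicates of the
response table are runs 4, 5 and 12 (the only rows forming near-identical
triples, whose means match the reported model constants).
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .doe import FactorSpec
from .peaks import ResponseTable
from .rsm import TERM_NAMES, QuadraticModel

__all__ = [
    "load_fixture",
    "STUDY_FACTORS",
    "CENTER_RUNS",
    "RESPONSE_NAMES",
    "NADFC_LIMITS",
]

#: The study's three factors with their uncoded levels.
STUDY_FACTORS = [
    FactorSpec("pct_B_initial", 0.0, 10.0, units="%"),
    FactorSpec("pct_B_end", 60.0, 100.0, units="%"),
    FactorSpec("pH", 3.0, 7.0, units="pH"),
]

#: 0-based indices of the center replicates in the 15-run response table.
CENTER_RUNS = (3, 4, 11)

RESPONSE_NAMES = [
    "Rs1-2", "Rs2-3", "Rs3-4", "Rs4-5", "Rs5-6", "Rs6-7", "Rs7-8", "time_min",
]

_RESPONSES_CSV = """\
run,Rs1-2,Rs2-3,Rs3-4,Rs4-5,Rs5-6,Rs6-7,Rs7-8,time_min
1,FOP,FOP,1.2280,0.9515,0.6610,1.6360,0.7855,19.09
2,0.2555,1.1254,1.5789,1.5465,3.0378,2.7325,0.3874,21.18
3,FOP,FOP,1.5295,1.0145,0.5500,2.5180,1.0330,20.27
4,3.1026,1.2854,0.8438,2.6014,FOP,1.2804,0.8706,17.84
5,3.0046,1.2852,0.8660,2.6402,FOP,1.2772,0.8807,17.84
6,FOP,1.1549,1.6432,1.1495,3.1962,1.5370,0.9020,19.56
7,3.0033,1.9175,1.1825,3.2517,0.1641,1.1538,FOP,18.60
8,3.4380,1.2154,0.8799,2.4530,FOP,1.2758,0.9002,19.20
9,2.4517,0.9708,2.6548,1.7886,1.0280,FOP,0.9276,14.70
10,FOP,FOP,1.2460,1.4690,0.5300,2.3685,1.0175,22.76
11,3.2329,0.9794,2.1677,1.8457,1.2248,0.6605,0.9197,17.15
12,3.1698,1.3190,0.8337,2.5400,FOP,1.2681,0.8802,17.82
13,1.0052,1.4346,1.1752,1.3097,4.0203,2.2164,0.8106,16.67
14,0.6670,1.8968,1.7036,1.2585,3.4432,1.0378,1.1120,16.25
15,FOP,FOP,1.0430,1.2720,3.1895,3.1895,1.3860,25.40
"""

# Reported coefficient matrix: rows follow TERM_NAMES, then fit metrics.
_COEFFICIENTS_CSV = """\
term,Rs1-2,Rs2-3,Rs3-4,Rs4-5,Rs5-6,Rs6-7,Rs7-8,time_min
constant,3.092,1.297,0.848,2.594,0.000,1.275,0.877,23.085
x1,-0.026,0.122,0.076,0.056,0.098,0.006,-0.121,-0.620
x2,-0.043,-0.051,0.384,-0.335,-0.008,-0.627,0.134,-3.039
x3,0.241,0.701,0.132,0.070,1.096,-0.274,-0.126,-0.617
x1x1,-0.020,-0.067,0.442,-0.140,0.044,-0.246,-0.084,-0.672
x1x2,-0.087,-0.178,0.046,-0.214,-0.097,-0.135,0.227,-0.774
x1x3,0.251,0.070,-0.188,0.154,0.201,0.132,-0.027,-0.025
x2x2,-0.041,0.041,0.432,-0.119,0.553,-0.257,-0.107,0.208
x2x3,0.103,0.193,-0.015,0.008,0.733,-0.035,0.331,0.085
x3x3,-2.821,-0.582,0.109,-1.218,2.030,1.131,0.147,0.366
R2,0.9743,0.9153,0.7414,0.9370,0.8794,0.9401,0.8679,0.9375
R2_adj,0.9281,0.7629,0.2758,0.8236,0.6624,0.8324,0.6301,0.8260
SE,0.4005,0.3234,0.4443,0.3008,0.8749,0.3461,0.1908,1.0064
MAE,0.1987,0.1477,0.1983,0.1392,0.3958,0.1577,0.0830,0.5456
"""

#: Terms the study flagged significant (p < 0.05) per response.
SIGNIFICANT_TERMS = {
    "Rs1-2": ["x3x3"],
    "Rs2-3": ["x3", "x3x3"],
    "Rs3-4": [],
    "Rs4-5": ["x2", "x3x3"],
    "Rs5-6": ["x3", "x3x3"],
    "Rs6-7": ["x1", "x3x3"],
    "Rs7-8": ["x2x3"],
    "time_min": ["x2"],
}

# Mean measured concentrations (mg/kg) in the nine commercial samples;
# blank cells were below detection.
_SAMPLES_CSV = """\
sample,ACE,BEN,SOR,SAC,TAR,CAF,SUN,ASP
01,181.97,,,,61.72,,5.33,446.96
02,140.86,,,,18.80,,8.11,495.24
03,185.71,,,,12.77,,,156.75
04,,77.87,42.50,117.97,,,,476.01
05,204.68,,,,15.66,,,163.25
06,491.17,,,,12.04,31.45,,188.11
07,,,,,,94.62,,274.82
08,70.68,,,,,66.17,,437.57
09,173.10,,,,10.51,22.06,,258.76
"""

#: Regulatory maximum concentrations (mg/kg) for powdered-drink additives.
NADFC_LIMITS = {
    "ACE": 600.0,
    "BEN": 600.0,
    "SOR": 1000.0,
    "SAC": 120.0,
    "TAR": 300.0,
    "CAF": 250.0,
    "SUN": 300.0,
    "ASP": 600.0,
}

_ALIASES = {
    "table1": "factors",
    "table2": "responses",
    "table3": "coefficients",
    "table5b": "samples",
}


def load_fixture(name: str):
    """Return one of the bundled study tables.

    ``factors``
        list of :class:`FactorSpec` (aliases: ``table1``).
    ``responses``
        the 15-run :class:`ResponseTable` with FOP markers (``table2``).
    ``coefficients``
        DataFrame of the reported coefficient matrix + fit metrics
        (``table3``).
    ``models``
        the coefficient matrix wrapped as :class:`QuadraticModel` objects.
    ``samples``
        DataFrame of measured sample concentrations, mg/kg (``table5b``).
    ``limits``
        dict of regulatory maxima, mg/kg.
    """
    key = _ALIASES.get(name, name)
    if key == "factors":
        return list(STUDY_FACTORS)
    if key == "responses":
        df = pd.read_csv(io.StringIO(_RESPONSES_CSV), dtype=str).drop(columns="run")
        return ResponseTable.from_frame(df)
    if key == "coefficients":
        return pd.read_csv(io.StringIO(_COEFFICIENTS_CSV), index_col="term")
    if key == "models":
        coefs = pd.read_csv(io.StringIO(_COEFFICIENTS_CSV), index_col="term")
        return [
            QuadraticModel.from_coefficients(c, coefs.loc[list(TERM_NAMES), c].to_numpy())
            for c in coefs.columns
        ]
    if key == "samples":
        return pd.read_csv(io.StringIO(_SAMPLES_CSV), index_col="sample")
    if key == "limits":
        return dict(NADFC_LIMITS)
    raise KeyError(
        f"unknown fixture {name!r}; choose from factors/responses/coefficients/"
        "models/samples/limits (aliases table1/table2/table3/table5b)"
    )
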