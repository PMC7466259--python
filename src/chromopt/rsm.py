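"""Second-order response-surface models on coded factors.

Each response y measured over a three-factor designed experiment is fitted
with the full second-order polynomial

    y = b0 + b1 x1 + b2 x2 + b3 x3
        + b11 x1^2 + b22 x2^2 + b33 x3^2
        + b12 x1 x2 + b13 x1 x3 + b23 x2 x3

by ordinary least squares on the coded (-1/0/+1) scale. Per-term p-values
come from two-sided t-tests of coefficient / standard error on the residual
degrees of freedom; terms with p below a chosen alpha can be kept in a
refitted reduced model.

A useful exact property of coded Box-Behnken data: the indicator of the
center runs equals 1 - (x1^2 + x2^2 + x3^2)/2, which lies in the model's
column span, so the fitted intercept always equals the mean of the
center-run responses. This holds for any assignment of the edge runs and
is exploited both in tests and to sanity-check externally reported
coefficient tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .doe import Design

__all__ = ["TERM_NAMES", "QuadraticModel", "design_matrix", "fit_full_quadratic"]

#: Term order used throughout: intercept, linear, then quadratics and
#: interactions interleaved per factor (x1x1, x1x2, x1x3, x2x2, x2x3, x3x3).
TERM_NAMES = (
    "constant",
    "x1",
    "x2",
    "x3",
    "x1x1",
    "x1x2",
    "x1x3",
    "x2x2",
    "x2x3",
    "x3x3",
)


def _monomials(point) -> np.ndarray:
    x1, x2, x3 = point
    return np.array(
        [1.0, x1, x2, x3, x1 * x1, x1 * x2, x1 * x3, x2 * x2, x2 * x3, x3 * x3]
    )


def design_matrix(coded: np.ndarray) -> np.ndarray:
    """Model matrix of the ten quadratic terms for coded points (n x 3)."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    return np.stack([_monomials(p) for p in coded])


@dataclass
class QuadraticModel:
    """A fitted (or externally supplied) second-order polynomial.

    ``coef`` follows :data:`TERM_NAMES` order. Inference fields are None
    for models built from a printed coefficient table rather than fitted
    here.
    """

    response_name: str
    coef: np.ndarray
    p_values: np.ndarray | None = None
    se_coef: np.ndarray | None = None
    r2: float | None = None
    r2_adj: float | None = None
    se: float | None = None
    mae: float | None = None
    n_obs: int | None = None
    df_resid: int | None = None
    terms: tuple[str, ...] = TERM_NAMES
    degenerate: bool = False  # zero residual variance; p-values conventional

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (len(self.terms),):
            raise ValueError(
                f"expected {len(self.terms)} coefficients, got {self.coef.shape}"
            )

    # convenient views -----------------------------------------------------
    @property
    def beta0(self) -> float:
        return float(self.coef[self.terms.index("constant")])

    def coef_full(self) -> np.ndarray:
        """Coefficients expanded to the full 10-term basis (zeros for dropped terms)."""
        full = np.zeros(len(TERM_NAMES))
        for name, b in zip(self.terms, self.coef):
            full[TERM_NAMES.index(name)] = b
        return full

    def predict(self, coded_point) -> float:
        """Evaluate the polynomial at one coded point."""
        return float(_monomials(coded_point) @ self.coef_full())

    def predict_many(self, coded: np.ndarray) -> np.ndarray:
        return design_matrix(coded) @ self.coef_full()

    def significant_terms(self, alpha: float = 0.05) -> list[str]:
        if self.p_values is None:
            raise ValueError("model carries no p-values")
        return [
            t
            for t, p in zip(self.terms, self.p_values)
            if t != "constant" and p < alpha
        ]

    @classmethod
    def from_coefficients(cls, response_name: str, coef) -> "QuadraticModel":
        """Wrap an externally reported 10-coefficient column (no inference)."""
        return cls(response_name=response_name, coef=np.asarray(coef, dtype=float))

    def summary_series(self):
        import pandas as pd

        full = self.coef_full()
        idx = list(TERM_NAMES) + ["R2", "R2_adj", "SE", "MAE"]
        vals = list(full) + [self.r2, self.r2_adj, self.se, self.mae]
        return pd.Series(vals, index=idx, name=self.response_name)


def _fit(X: np.ndarray, y: np.ndarray, terms: tuple[str, ...], name: str) -> QuadraticModel:
    n, p = X.shape
    if n < p + 1:
        raise ValueError(
            f"{n} observations cannot estimate {p} parameters with residual df"
        )
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError(
            f"design is rank-deficient for the {p}-term model"
        )
    res = sm.OLS(y, X).fit()
    resid = y - res.fittedvalues
    sse = float(resid @ resid)
    df_resid = n - p
    se = float(np.sqrt(sse / df_resid))
    mae = float(np.abs(resid).mean())
    degenerate = sse <= 1e-24 * max(1.0, float(y @ y))
    if degenerate:
        pvals = np.where(np.abs(res.params) > 0, 0.0, 1.0)
    else:
        pvals = np.asarray(res.pvalues)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    r2_adj = (
        r2
        if sst == 0
        else 1.0 - (1.0 - r2) * (n - 1) / df_resid
    )
    return QuadraticModel(
        response_name=name,
        coef=np.asarray(res.params),
        p_values=pvals,
        se_coef=np.asarray(res.bse),
        r2=r2,
        r2_adj=r2_adj,
        se=se,
        mae=mae,
        n_obs=n,
        df_resid=df_resid,
        terms=terms,
        degenerate=degenerate,
    )


def fit_full_quadratic(design: Design, y, response_name: str = "y") -> QuadraticModel:
    """Fit the full 10-term second-order model to one response column.

    ``y`` may be a numeric array or a list containing FOP markers; marker
    cells are encoded as 0 (a fully overlapped pair has no measurable
    separation). Fitting is by OLS on the coded design.
    """
    from .peaks import FOP, FOP_ENCODING

    yv = np.array(
        [FOP_ENCODING if isinstance(v, str) and v.upper() == FOP else float(v) for v in y]
    )
    if len(yv) != design.n_runs:
        raise ValueError(
            f"response length {len(yv)} != design size {design.n_runs}"
        )
    X = design_matrix(design.coded_matrix())
    return _fit(X, yv, TERM_NAMES, response_name)


def fit_all(design: Design, table, fop_value: float | None = None) -> list[QuadraticModel]:
    """Fit the full quadratic to every column of a :class:`ResponseTable`."""
    from .peaks import FOP_ENCODING

    enc = table.encoded(FOP_ENCODING if fop_value is None else fop_value)
    return [
        fit_full_quadratic(design, enc[c].to_numpy(), response_name=c)
        for c in enc.columns
    ]


def reduce_model(
    model: QuadraticModel, design: Design, y, alpha: float = 0.05
) -> QuadraticModel:
    """Refit keeping the intercept plus terms significant at ``alpha``.

    Model hierarchy is deliberately not enforced: a pure quadratic term may
    stay while its linear parent is dropped, matching common RSM software
    output. With ``alpha >= 1`` the full model is returned unchanged.
    """
    if not 0 < alpha:
        raise ValueError("alpha must be positive")
    if alpha >= 1:
        return model
    if model.p_values is None:
        raise ValueError("cannot reduce a model without p-values")
    from .peaks import FOP, FOP_ENCODING

    yv = np.array(
        [FOP_ENCODING if isinstance(v, str) and v.upper() == FOP else float(v) for v in y]
    )
    keep = [
        t
        for t, p in zip(model.terms, model.p_values)
        if t == "constant" or p < alpha
    ]
    cols = [TERM_NAMES.index(t) for t in keep]
    X = design_matrix(design.coded_matrix())[:, cols]
    return _fit(X, yv, tuple(keep), model.response_name)


def models_to_frame(models: list[QuadraticModel]):
    """Coefficient table (terms + fit metrics as rows, responses as columns)."""
    import pandas as pd

    return pd.DataFrame({m.response_name: m.summary_series() for m in models})
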