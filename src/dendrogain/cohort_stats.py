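"""Per-subject cohort statistics: Pearson correlation with linear
regression, IQ-group split, and two-sample t-test.

Because several neurons are measured per subject, all correlations operate
on mean parameter values per subject.  The association between two
per-subject variables is summarised by the Pearson coefficient r (with a
two-sided p-value from the t distribution on n−2 degrees of freedom), the
least-squares regression line, and the pointwise 95% confidence band of
the fit.  Group contrasts split subjects at the conventional IQ = 100
boundary and use an equal-variance Student t-test (Welch available behind
a flag).  No multiple-testing correction is applied, matching the
single-comparison reporting convention; output metadata says so.

The modelling interface follows the statsmodels idiom::

    res = CohortAssociation.from_dataframe(df, "iq", "tdl").fit()
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "TTestResult",
    "DegenerateInputError",
    "InsufficientDataError",
    "pearson_regression",
    "split_by_iq",
    "two_sample_ttest",
    "CohortAssociation",
    "CohortAssociationResults",
]


class DegenerateInputError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation + regression line for per-subject means."""

    r: float
    p_value: float
    n: int
    slope: float
    intercept: float
    x_mean: float
    sxx: float
    residual_se: float  # sqrt(SSE / (n-2))

    @property
    def r2(self) -> float:
        return self.r**2

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def confidence_band(self, x, alpha: float = 0.05):
        """Pointwise (1−alpha) confidence band of the fitted mean response.

        Returns (lower, upper) arrays at the query points ``x``.
        """
        x = np.asarray(x, dtype=float)
        yhat = self.predict(x)
        tcrit = sps.t.ppf(1 - alpha / 2, self.n - 2)
        half = tcrit * self.residual_se * np.sqrt(
            1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        )
        return yhat - half, yhat + half


def pearson_regression(x, y) -> CorrelationResult:
    """Pearson r, two-sided p (t distribution, df = n−2) and the
    least-squares line for two per-subject vectors.

    Raises :class:`DegenerateInputError` for zero variance and
    :class:`InsufficientDataError` for n < 3 or non-finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 subjects")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    fit = sps.linregress(x, y)
    n = len(x)
    resid = y - (fit.intercept + fit.slope * x)
    sse = float(np.sum(resid**2))
    return CorrelationResult(
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        x_mean=float(np.mean(x)),
        sxx=float(np.sum((x - np.mean(x)) ** 2)),
        residual_se=np.sqrt(sse / (n - 2)),
    )


def split_by_iq(records: pd.DataFrame, iq_column: str = "iq") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split subject records into a low (IQ < 100) and a high (IQ > 100)
    group; a score of exactly 100 is routed to the high group with a
    warning (the convention is documented, such scores are rare)."""
    iq = records[iq_column]
    if (iq == 100).any():
        warnings.warn("IQ exactly 100 assigned to the high group", stacklevel=2)
    low = records[iq < 100]
    high = records[iq >= 100]
    return low, high


@dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    n_a: int
    n_b: int
    equal_var: bool


def two_sample_ttest(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sided Student t-test on per-subject means (equal-variance by
    default; set ``equal_var=False`` for Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 subjects")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        t=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        equal_var=equal_var,
    )


# ---------------------------------------------------------------------------
# statsmodels-style front end


class CohortAssociation:
    """Pearson/regression association model between two per-subject
    variables, built from vectors or a cohort DataFrame."""

    def __init__(self, x, y, xname: str = "x", yname: str = "y"):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.xname = xname
        self.yname = yname

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str, y: str) -> "CohortAssociation":
        sub = df[[x, y]].dropna()
        return cls(sub[x].to_numpy(), sub[y].to_numpy(), xname=x, yname=y)

    def fit(self) -> "CohortAssociationResults":
        return CohortAssociationResults(self, pearson_regression(self.x, self.y))


class CohortAssociationResults:
    """Fitted association: exposes the :class:`CorrelationResult` fields
    plus a ``summary()`` table and a scatter/regression plot."""

    def __init__(self, model: CohortAssociation, result: CorrelationResult):
        self.model = model
        self._res = result

    def __getattr__(self, name):
        return getattr(self._res, name)

    @property
    def result(self) -> CorrelationResult:
        return self._res

    def summary(self) -> str:
        r = self._res
        lines = [
            "Cohort association (Pearson correlation + linear regression)",
            "=" * 60,
            f"x: {self.model.xname:<20s} y: {self.model.yname}",
            f"n subjects          {r.n:>10d}",
            f"Pearson r           {r.r:>10.3f}",
            f"R^2                 {r.r2:>10.3f}",
            f"p-value (2-sided)   {r.p_value:>10.4g}",
            f"slope               {r.slope:>10.4g}",
            f"intercept           {r.intercept:>10.4g}",
            "-" * 60,
            "note: single comparison, no multiple-testing correction",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, band_alpha: float = 0.05):
        """Scatter with the regression line and 95% confidence band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.x, self.model.y
        xs = np.linspace(x.min(), x.max(), 100)
        lo, hi = self._res.confidence_band(xs, alpha=band_alpha)
        ax.fill_between(xs, lo, hi, alpha=0.25, lw=0)
        ax.plot(xs, self._res.predict(xs), "-")
        ax.plot(x, y, "o", ms=5)
        ax.set_xlabel(self.model.xname)
        ax.set_ylabel(self.model.yname)
        ax.set_title(f"r = {self._res.r:.2f}, p = {self._res.p_value:.3g}")
        return ax
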