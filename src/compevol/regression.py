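"""Log transforms and abundance->rate regressions.

Both log10(abundance) and log10(omega) carry measurement error, so the
primary fit is a Deming errors-in-variables regression with error-variance
ratio delta (delta=1 gives orthogonal regression; delta -> infinity recovers
ordinary least squares). A LOESS smoother provides the assumption-free
robustness path. Residuals are vertical (in the rate axis) by default: they
are the "abundance-controlled" rate measure consumed downstream; orthogonal
residuals are available as an option.

Because rate-estimation software reports very low rates as a shared non-zero
floor, omega distributions are zero-inflated; log10(omega + epsilon) with a
small pseudo-count keeps those genes in the analysis without dominating it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data import GeneRecord

__all__ = [
    "TransformSpec",
    "RegressionFit",
    "LoessFit",
    "ResidualRecord",
    "log_omega",
    "pseudocount_from_ds",
    "transform_records",
    "deming_fit",
    "ols_fit",
    "fit_residuals",
    "loess_fit",
    "linear_vs_quadratic",
    "slope_equality_test",
]


@dataclass(frozen=True)
class TransformSpec:
    """Log10 transform with a pseudo-count applied to omega only.

    Abundance is strictly positive, so it is logged without a pseudo-count;
    omega can be zero (or floored), so log10(omega + epsilon) is used.
    """

    epsilon: float = 0.01
    base: float = 10.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def log_omega(omega: float, spec: TransformSpec = TransformSpec()) -> float:
    """log10(omega + epsilon); strictly increasing in omega."""
    if omega < 0:
        raise ValueError(f"omega must be nonnegative, got {omega}")
    return math.log10(omega + spec.epsilon)


def pseudocount_from_ds(ds_values: Sequence[float]) -> float:
    """The stated data-driven pseudo-count rule, 1/min(dS).

    The rule is internally puzzling (a typical min dS of ~0.01 gives a
    pseudo-count of ~100), so it is provided verbatim for transparency but
    epsilon defaults to 0.01 directly.
    """
    arr = np.asarray(ds_values, dtype=float)
    arr = arr[np.isfinite(arr) & (arr > 0)]
    if arr.size == 0:
        raise ValueError("no positive finite dS values")
    return float(1.0 / arr.min())


@dataclass
class RegressionFit:
    """A fitted linear abundance->log-rate relationship."""

    method: str  # "deming" or "ols"
    slope: float
    intercept: float
    delta: Optional[float]
    transform: TransformSpec
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class ResidualRecord:
    gene_id: str
    x: float
    y: float
    residual: float


def transform_records(records: Sequence[GeneRecord], spec: TransformSpec = TransformSpec()):
    """(gene_ids, x, y, skipped): x=log10 abundance, y=log10(omega+eps).

    Records missing abundance or omega are excluded and listed in
    ``skipped`` as (gene_id, reason).
    """
    ids, xs, ys, skipped = [], [], [], []
    for r in records:
        if r.abundance is None:
            skipped.append((r.gene_id, "no_abundance"))
            continue
        if r.omega is None:
            skipped.append((r.gene_id, "no_omega"))
            continue
        ids.append(r.gene_id)
        xs.append(math.log10(r.abundance))
        ys.append(log_omega(r.omega, spec))
    return ids, np.asarray(xs), np.asarray(ys), skipped


def _moments(x: np.ndarray, y: np.ndarray):
    xbar, ybar = x.mean(), y.mean()
    dx, dy = x - xbar, y - ybar
    return xbar, ybar, float(dx @ dx) / x.size, float(dy @ dy) / x.size, float(dx @ dy) / x.size


def deming_fit(
    x: Sequence[float],
    y: Sequence[float],
    delta: float = 1.0,
    transform: TransformSpec = TransformSpec(),
) -> RegressionFit:
    """Moment-based Deming estimator with error-variance ratio delta.

    slope = (s_yy - delta*s_xx + sqrt((s_yy - delta*s_xx)^2 + 4*delta*s_xy^2))
            / (2*s_xy), intercept = ybar - slope*xbar. With s_xy = 0 the
    delta-scaled principal axis decides: a horizontal major axis gives slope
    0, a vertical one is degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if delta <= 0:
        raise ValueError("delta must be positive")
    xbar, ybar, sxx, syy, sxy = _moments(x, y)
    if sxx == 0:
        raise ValueError("x values are all equal; slope is undefined")
    if sxy == 0:
        if delta * sxx >= syy:
            slope = 0.0
        else:
            raise ValueError("principal axis is vertical (s_xy = 0 and s_yy > delta*s_xx)")
    else:
        a = syy - delta * sxx
        slope = (a + math.sqrt(a * a + 4.0 * delta * sxy * sxy)) / (2.0 * sxy)
    intercept = ybar - slope * xbar
    return RegressionFit("deming", float(slope), float(intercept), delta, transform, x.size)


def ols_fit(
    x: Sequence[float], y: Sequence[float], transform: TransformSpec = TransformSpec()
) -> RegressionFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    xbar, ybar, sxx, _, sxy = _moments(x, y)
    if sxx == 0:
        raise ValueError("x values are all equal; slope is undefined")
    slope = sxy / sxx
    return RegressionFit("ols", float(slope), float(ybar - slope * xbar), None, transform, x.size)


def fit_residuals(records: Sequence[GeneRecord], fit, orthogonal: bool = False):
    """Per-gene residuals against a fitted curve.

    ``fit`` is a RegressionFit or LoessFit; the transform stored in the fit
    is reapplied so residuals live on the fitted scale. Vertical residuals
    y - yhat(x) by default; ``orthogonal=True`` rescales linear-fit
    residuals to signed perpendicular distances. Genes missing abundance or
    omega are excluded (returned in the skip log).
    """
    ids, x, y, skipped = transform_records(records, fit.transform)
    yhat = fit.predict(x)
    res = y - yhat
    if orthogonal:
        if not isinstance(fit, RegressionFit):
            raise ValueError("orthogonal residuals are defined for linear fits only")
        res = res / math.sqrt(1.0 + fit.slope * fit.slope)
    out = [ResidualRecord(g, float(xi), float(yi), float(ri)) for g, xi, yi, ri in zip(ids, x, y, res)]
    return out, skipped


@dataclass
class LoessFit:
    """Tricube-weighted local polynomial smoother (no robustness iterations).

    ``span`` is the fraction of points in each local neighbourhood; the local
    polynomial degree is 1 or 2. Deterministic for fixed inputs. Prediction
    at new x re-solves the local weighted fit there.
    """

    x: np.ndarray
    y: np.ndarray
    span: float
    degree: int
    transform: TransformSpec = field(default_factory=TransformSpec)
    method: str = "loess"

    fitted: np.ndarray = field(init=False)
    residuals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.x.size
        if n < 10:
            raise ValueError(f"LOESS needs at least 10 points, got {n}")
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        if self.span * n < self.degree + 2:
            raise ValueError(
                f"span {self.span} too small: span*n = {self.span * n:.2f} < degree+2"
            )
        self.fitted = self.predict(self.x)
        self.residuals = self.y - self.fitted

    @property
    def n(self) -> int:
        return self.x.size

    def predict(self, xnew):
        xnew = np.atleast_1d(np.asarray(xnew, dtype=float))
        k = max(int(math.ceil(self.span * self.x.size)), self.degree + 2)
        out = np.empty(xnew.size)
        for i, x0 in enumerate(xnew):
            d = np.abs(self.x - x0)
            nn = np.argpartition(d, k - 1)[:k]
            dmax = d[nn].max()
            if dmax == 0:
                out[i] = self.y[nn].mean()
                continue
            u = d[nn] / dmax
            w = np.clip(1.0 - u**3, 0.0, None) ** 3
            if w.sum() <= 0 or np.count_nonzero(w) < self.degree + 1:
                out[i] = self.y[nn].mean()
                continue
            coeffs = np.polynomial.polynomial.polyfit(
                self.x[nn] - x0, self.y[nn], deg=self.degree, w=np.sqrt(w)
            )
            out[i] = coeffs[0]
        return out


def loess_fit(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    degree: int = 1,
    transform: TransformSpec = TransformSpec(),
) -> LoessFit:
    """Fit the LOESS smoother; see LoessFit."""
    return LoessFit(np.asarray(x, float), np.asarray(y, float), span, degree, transform)


@dataclass
class NestedFTest:
    f: float
    df: tuple[int, int]
    p: float


def linear_vs_quadratic(x: Sequence[float], r: Sequence[float]) -> NestedFTest:
    """Nested OLS F-test of r ~ x against r ~ x + x^2.

    Used on residuals of the pooled linear fit: a concave abundance->rate
    relationship leaves an n-shaped residual pattern that the quadratic term
    picks up.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    n = x.size
    if n <= 4:
        raise ValueError("need more than 4 points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal")
    X1 = np.column_stack([np.ones(n), x])
    X2 = np.column_stack([np.ones(n), x, x * x])
    rss1 = float(np.linalg.lstsq(X1, r, rcond=None)[1].sum()) if n > 2 else 0.0
    b2, res2, rank2, _ = np.linalg.lstsq(X2, r, rcond=None)
    if rank2 < 3:
        raise ValueError("design is collinear; quadratic term is aliased")
    rss2 = float(res2.sum()) if res2.size else float(np.sum((r - X2 @ b2) ** 2))
    df2 = n - 3
    # guard degenerate fits (both models exact) against float noise
    tol = 1e-12 * float(r @ r) + 1e-300
    num = max(rss1 - rss2, 0.0)
    if num <= tol:
        f = 0.0
    elif rss2 <= tol:
        f = math.inf
    else:
        f = num / (rss2 / df2)
    p = float(stats.f.sf(f, 1, df2)) if math.isfinite(f) else 0.0
    return NestedFTest(float(f), (1, df2), p)


@dataclass
class SlopeEqualityResult:
    f: float
    df: tuple[int, int]
    p: float
    ols_slopes: list[float]
    deming_slopes: list[float]


def slope_equality_test(
    groups: Sequence[tuple[Sequence[float], Sequence[float]]], delta: float = 1.0
) -> SlopeEqualityResult:
    """Test equality of regression slopes across groups.

    The p-value comes from the OLS interaction F-test (full model with
    per-group slopes vs common slope); per-group Deming slopes are reported
    alongside for description, mirroring how the fits themselves are made.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    xs, ys, labels = [], [], []
    ols_slopes, deming_slopes = [], []
    for gi, (x, y) in enumerate(groups):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3:
            raise ValueError(f"group {gi} has fewer than 3 points")
        if np.ptp(x) == 0:
            raise ValueError(f"group {gi} has degenerate x")
        xs.append(x)
        ys.append(y)
        labels.append(np.full(x.size, gi))
        ols_slopes.append(ols_fit(x, y).slope)
        deming_slopes.append(deming_fit(x, y, delta=delta).slope)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    g = np.concatenate(labels)
    n, k = x.size, len(groups)
    dummies = np.column_stack([(g == j).astype(float) for j in range(1, k)])
    X_red = np.column_stack([np.ones(n), x, dummies])
    X_full = np.column_stack([X_red, dummies * x[:, None]])
    rss_red = float(np.sum((y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]) ** 2))
    rss_full = float(np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2))
    df1 = k - 1
    df2 = n - 2 * k
    if df2 <= 0:
        raise ValueError("too few points for the interaction test")
    f = max(rss_red - rss_full, 0.0) / df1 / (rss_full / df2) if rss_full > 0 else math.inf
    p = float(stats.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    return SlopeEqualityResult(float(f), (df1, df2), p, ols_slopes, deming_slopes)
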