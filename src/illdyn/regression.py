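"""Entropy-outcome association: loess visualization, OLS, and RCS adjustment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm


class RegressionError(ValueError):
    pass


@dataclass
class SmoothCurve:
    x: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int


@dataclass
class AssociationResult:
    """Entropy coefficient with Wald 95% CI from a least-squares fit."""

    beta_entropy: float
    ci_low: float
    ci_high: float
    p_value: float
    r_squared: float
    intercept: float
    knots: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta_entropy <= self.ci_high:
            raise RegressionError("CI does not bracket the point estimate")

    def to_dict(self) -> dict:
        return {
            "beta_entropy": self.beta_entropy,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "intercept": self.intercept,
            "knots": list(self.knots) if self.knots else None,
        }


def loess_curve(
    x,
    y,
    span: float = 0.75,
    degree: int = 1,
    grid=None,
    n_grid: int = 100,
) -> SmoothCurve:
    """Locally weighted least-squares smoother with tricube weights.

    At each grid point the nearest ``ceil(span * n)`` observations are fit
    with a weighted polynomial of the given degree (default locally
    linear) and the fit is evaluated at the point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise RegressionError("need at least 10 observations")
    if not 0 < span <= 1:
        raise RegressionError("span must be in (0, 1]")
    if degree not in (0, 1, 2):
        raise RegressionError("degree must be 0, 1 or 2")
    if np.ptp(x) == 0:
        raise RegressionError("degenerate x: all values equal")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    q = max(degree + 2, int(np.ceil(span * n)))
    q = min(q, n)
    fitted = np.empty(grid.size)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        if w.sum() == 0:
            w = np.ones_like(w)
        X = np.vander(x[idx] - x0, degree + 1, increasing=True)
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y[idx], rcond=None)
        fitted[i] = beta[0]
    return SmoothCurve(grid, fitted, span, degree)


def _wald_result(model_fit, knots=None) -> AssociationResult:
    ci = model_fit.conf_int(alpha=0.05)
    return AssociationResult(
        beta_entropy=float(model_fit.params[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=float(model_fit.pvalues[1]),
        r_squared=float(model_fit.rsquared),
        intercept=float(model_fit.params[0]),
        knots=knots,
    )


def fit_univariate(composite, entropy) -> AssociationResult:
    """OLS of the composite on entropy with homoskedastic Wald 95% CI."""
    y = np.asarray(composite, dtype=float)
    x = np.asarray(entropy, dtype=float)
    if y.size != x.size:
        raise RegressionError("length mismatch")
    if y.size < 3:
        raise RegressionError("need at least 3 observations")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise RegressionError("non-finite inputs")
    X = sm.add_constant(x)
    return _wald_result(sm.OLS(y, X).fit())


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis with 3 knots: two columns.

    Column 0 is the linear term; column 1 is the restricted cubic term

        [(x-k1)+^3 - (x-k2)+^3 (k3-k1)/(k3-k2) + (x-k3)+^3 (k2-k1)/(k3-k2)]
        / (k3-k1)^2

    which makes the fitted spline linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    k1, k2, k3 = (float(k) for k in knots)
    if not k1 < k2 < k3:
        raise RegressionError("knots must be strictly increasing")
    pos = lambda t: np.maximum(t, 0.0) ** 3
    nonlinear = (
        pos(x - k1)
        - pos(x - k2) * (k3 - k1) / (k3 - k2)
        + pos(x - k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2
    return np.column_stack([x, nonlinear])


def default_knots(x) -> tuple[float, float, float]:
    """3-knot placement at the 0.10 / 0.50 / 0.90 quantiles."""
    q = np.quantile(np.asarray(x, float), [0.10, 0.50, 0.90])
    return (float(q[0]), float(q[1]), float(q[2]))


def fit_adjusted(composite, entropy, mean_score, knots=None) -> AssociationResult:
    """OLS of the composite on entropy plus an RCS(3) in mean score.

    If the adjuster is constant its spline columns are dropped and the
    fit degenerates to the univariate model. A rank-deficient design
    raises with a diagnostic.
    """
    y = np.asarray(composite, dtype=float)
    h = np.asarray(entropy, dtype=float)
    ms = np.asarray(mean_score, dtype=float)
    if not (y.size == h.size == ms.size):
        raise RegressionError("length mismatch")
    if np.ptp(ms) == 0:
        return fit_univariate(y, h)
    if knots is None:
        knots = default_knots(ms)
    k1, k2, k3 = knots
    if not k1 < k2 < k3:
        raise RegressionError("knots must be strictly increasing")
    spline = rcs_basis(ms, knots)
    # drop spline columns that are constant over the observed scores
    keep = [j for j in range(spline.shape[1]) if np.ptp(spline[:, j]) > 0]
    X = sm.add_constant(np.column_stack([h] + [spline[:, j] for j in keep]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RegressionError(
            "collinear design: entropy and spline columns are linearly dependent"
        )
    return _wald_result(sm.OLS(y, X).fit(), knots=tuple(knots))
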