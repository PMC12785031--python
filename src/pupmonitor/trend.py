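"""Smooth abundance-vs-year trends with derivative-based turning points.

Pup abundance trajectories are smoothed with a penalized cubic B-spline
(a small GAM with a single smooth of year). The fit minimises

    ||y - X beta||^2  +  lambda * beta' S beta ,

where X is a cubic B-spline basis (default dimension 10) on the observed
year range and S is the exact integrated-squared-second-derivative penalty
matrix, S_ij = Int B_i''(x) B_j''(x) dx. The null space of S is precisely
the straight lines, so linear data are reproduced exactly at any lambda.
The smoothing parameter is chosen by generalized cross-validation (GCV) by
default, or by a REML-type criterion. Two response families are supported:
Gaussian with identity link, and gamma with log link (fitted by penalized
IRLS; for the gamma/log pair the IRLS working weights are identically 1).

Inference uses the Bayesian posterior covariance of the spline
coefficients, V = (X'X + lambda S)^{-1} * scale. Pointwise 95% intervals
for the fitted curve are reported on the response scale; the first
derivative of the smooth and its interval are reported on the linear-
predictor scale, where a sign change of the derivative point estimate
marks a *turning point* of the trajectory. A turning point is flagged
significant when the derivative interval excludes zero on at least one
grid point adjacent to the sign change; maximal runs of grid points whose
interval excludes zero are reported as significant increase/decline
periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

__all__ = [
    "TrendFit",
    "DerivativeSeries",
    "TurningPoint",
    "fit_trend",
    "derivative",
    "find_turning_points",
    "significant_periods",
    "trend_frame",
]

Family = Literal["gaussian_identity", "gamma_log"]


@dataclass(frozen=True)
class TrendFit:
    """A fitted penalized-spline smooth of abundance on year."""

    colony: str
    family: str
    years: np.ndarray
    values: np.ndarray
    knots: np.ndarray = field(repr=False)
    coef: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    lam: float
    edf: float
    scale: float
    df_resid: float
    basis_dim: int
    grid: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    ci_lower: np.ndarray = field(repr=False)
    ci_upper: np.ndarray = field(repr=False)

    def predict(self, x) -> np.ndarray:
        """Fitted mean on the response scale at years ``x`` (in range)."""
        eta = _design(np.asarray(x, float), self.knots) @ self.coef
        return np.exp(eta) if self.family == "gamma_log" else eta


@dataclass(frozen=True)
class DerivativeSeries:
    """First derivative of the smooth (linear-predictor scale) with CI."""

    grid: np.ndarray
    deriv: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    significant: np.ndarray  # True where the CI excludes zero


@dataclass(frozen=True)
class TurningPoint:
    """A sign change of the trend's first derivative.

    Reported as the bracketing pair of grid years, e.g. (1995.25, 1995.5),
    in the spirit of "1995/1996"-style reporting; not an interpolated
    crossing time.
    """

    interval: tuple[float, float]
    direction: str  # positive_to_negative | negative_to_positive
    significant: bool


# ---------------------------------------------------------------------------
# basis and penalty


def _knots(lo: float, hi: float, basis_dim: int) -> np.ndarray:
    """Clamped cubic knot vector giving ``basis_dim`` basis functions."""
    if basis_dim < 4:
        raise ValueError(f"basis_dim must be >= 4, got {basis_dim}")
    interior = np.linspace(lo, hi, basis_dim - 2)[1:-1]
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _design(x: np.ndarray, knots: np.ndarray, deriv: int = 0) -> np.ndarray:
    nb = len(knots) - 4
    if deriv == 0:
        return BSpline.design_matrix(x, knots, 3, extrapolate=False).toarray()
    return BSpline(knots, np.eye(nb), 3).derivative(deriv)(x)


def _penalty(knots: np.ndarray) -> np.ndarray:
    """Exact Int B_i'' B_j'' dx via 3-point Gauss rule per knot span.

    B'' of a cubic is piecewise linear, so the quadratic integrand is
    integrated exactly.
    """
    nb = len(knots) - 4
    spans = np.unique(knots)
    gx, gw = np.polynomial.legendre.leggauss(3)
    S = np.zeros((nb, nb))
    for a, b in zip(spans[:-1], spans[1:]):
        h = 0.5 * (b - a)
        x = a + h * (gx + 1.0)
        B2 = _design(x, knots, deriv=2)
        S += h * (B2.T * gw) @ B2
    return S


# ---------------------------------------------------------------------------
# fitting


def _penalized_solve(X, y, S, lam):
    A = X.T @ X + lam * S
    beta = np.linalg.solve(A, X.T @ y)
    return beta, A


def _edf(X, S, lam) -> float:
    A = X.T @ X + lam * S
    return float(np.trace(np.linalg.solve(A, X.T @ X)))


def _gcv(X, y, S, lam) -> float:
    beta, _ = _penalized_solve(X, y, S, lam)
    resid = y - X @ beta
    n = len(y)
    tr = _edf(X, S, lam)
    denom = max(n - tr, 1e-8)
    return n * float(resid @ resid) / denom**2


def _reml(X, y, S, lam) -> float:
    """Negative restricted log-likelihood (Gaussian, variance profiled).

    The penalty null space (dimension 2: straight lines) is treated as
    fixed effects; |lam*S| is the product of the nonzero eigenvalues.
    """
    n, p = X.shape
    beta, A = _penalized_solve(X, y, S, lam)
    resid = y - X @ beta
    pen = float(beta @ S @ beta)
    ev = np.linalg.eigvalsh(S)
    rank = int((ev > ev[-1] * 1e-10).sum())
    sig2 = (float(resid @ resid) + lam * pen) / max(n - (p - rank), 1)
    _, logdet_A = np.linalg.slogdet(A)
    logdet_S = rank * np.log(lam) + np.sum(np.log(ev[-rank:]))
    return 0.5 * (
        (float(resid @ resid) + lam * pen) / sig2
        + (n - (p - rank)) * np.log(sig2)
        + logdet_A
        - logdet_S
    )


def _choose_lambda(X, y, S, criterion: str) -> float:
    score = _gcv if criterion == "gcv" else _reml
    grid = np.logspace(-7, 9, 33)
    vals = [score(X, y, S, l) for l in grid]
    i = int(np.argmin(vals))
    lo = np.log(grid[max(i - 1, 0)])
    hi = np.log(grid[min(i + 1, len(grid) - 1)])
    if lo == hi:
        return float(grid[i])
    res = optimize.minimize_scalar(
        lambda t: score(X, y, S, np.exp(t)), bounds=(lo, hi), method="bounded"
    )
    return float(np.exp(res.x))


def fit_trend(
    years: Sequence[float],
    estimates: Sequence[float],
    family: Family = "gaussian_identity",
    basis_dim: int = 10,
    criterion: str = "gcv",
    colony: str = "",
    grid_step: float = 0.25,
    ci_level: float = 0.95,
    max_irls_iter: int = 100,
    lam: float | None = None,
) -> TrendFit:
    """Penalized cubic-spline smooth of abundance estimates on year.

    Needs at least 6 distinct years; gamma_log additionally needs strictly
    positive estimates. The smoothing parameter is selected by GCV
    (default) or REML on the (working) linear model; pass ``lam`` to fix
    it instead.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(estimates, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("years and estimates must be 1-D and equal length")
    if np.unique(x).size < 6:
        raise ValueError("need at least 6 distinct years to fit a smooth")
    if np.any(np.diff(np.sort(x)) < 0):
        raise ValueError("years must be sortable")
    if family not in ("gaussian_identity", "gamma_log"):
        raise ValueError(f"unknown family {family!r}")
    if criterion not in ("gcv", "reml"):
        raise ValueError(f"criterion must be gcv or reml, got {criterion!r}")
    if family == "gamma_log" and np.any(y <= 0):
        raise ValueError("gamma_log requires strictly positive estimates")
    order = np.argsort(x)
    x, y = x[order], y[order]
    knots = _knots(x[0], x[-1], basis_dim)
    X = _design(x, knots)
    S = _penalty(knots)
    n = len(y)

    fixed_lam = lam
    if family == "gaussian_identity":
        lam = fixed_lam if fixed_lam is not None else _choose_lambda(X, y, S, criterion)
        beta, A = _penalized_solve(X, y, S, lam)
        edf = _edf(X, S, lam)
        resid = y - X @ beta
        scale = float(resid @ resid) / max(n - edf, 1.0)
    else:
        # Penalized IRLS; gamma/log working weights are identically 1, so
        # each step is an unweighted penalized LS on the working response
        # z = eta + (y - mu)/mu ("performance iteration" for lambda).
        eta = np.log(y)
        lam = None
        for _ in range(max_irls_iter):
            mu = np.exp(eta)
            z = eta + (y - mu) / mu
            lam = fixed_lam if fixed_lam is not None else _choose_lambda(X, z, S, criterion)
            beta, A = _penalized_solve(X, z, S, lam)
            eta_new = X @ beta
            if np.max(np.abs(eta_new - eta)) < 1e-10:
                eta = eta_new
                break
            eta = eta_new
        else:
            raise RuntimeError(
                f"IRLS did not converge in {max_irls_iter} iterations "
                f"(last lambda {lam:.3g})"
            )
        edf = _edf(X, S, lam)
        mu = np.exp(eta)
        scale = float(np.sum(((y - mu) / mu) ** 2)) / max(n - edf, 1.0)

    cov = np.linalg.inv(X.T @ X + lam * S) * scale
    df_resid = max(n - edf, 1.0)
    grid = np.arange(x[0], x[-1] + grid_step / 2, grid_step)
    grid = np.minimum(grid, x[-1])
    Xg = _design(grid, knots)
    eta_g = Xg @ beta
    se_g = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov, Xg), 0.0))
    # t quantile on the residual df: n is small (a few dozen surveys) and
    # the scale is estimated, so a plain z interval undercovers
    z = stats.t.ppf(0.5 + ci_level / 2, df_resid)
    if family == "gamma_log":
        fitted = np.exp(eta_g)
        lo, hi = np.exp(eta_g - z * se_g), np.exp(eta_g + z * se_g)
    else:
        fitted = eta_g
        lo, hi = eta_g - z * se_g, eta_g + z * se_g
    return TrendFit(
        colony=colony,
        family=family,
        years=x,
        values=y,
        knots=knots,
        coef=beta,
        cov=cov,
        lam=float(lam),
        edf=float(edf),
        scale=float(scale),
        df_resid=float(df_resid),
        basis_dim=basis_dim,
        grid=grid,
        fitted=fitted,
        ci_lower=lo,
        ci_upper=hi,
    )


def derivative(
    fit: TrendFit,
    grid_step: float | None = None,
    ci_level: float = 0.95,
    n_draws: int = 0,
    rng: np.random.Generator | None = None,
) -> DerivativeSeries:
    """Analytic first derivative of the smooth with pointwise CI.

    Computed on the linear-predictor scale. The default CI is the delta
    method from the coefficient posterior covariance; set ``n_draws`` > 0
    to use posterior simulation of the coefficients instead (a cross-check
    of the analytic interval).
    """
    grid = (
        fit.grid
        if grid_step is None
        else np.minimum(
            np.arange(fit.years[0], fit.years[-1] + grid_step / 2, grid_step),
            fit.years[-1],
        )
    )
    D = _design(grid, fit.knots, deriv=1)
    d = D @ fit.coef
    z = stats.t.ppf(0.5 + ci_level / 2, fit.df_resid)
    if n_draws > 0:
        rng = np.random.default_rng() if rng is None else rng
        draws = rng.multivariate_normal(fit.coef, fit.cov, size=n_draws, method="svd")
        sims = draws @ D.T
        alpha = 0.5 - ci_level / 2
        lo = np.quantile(sims, alpha, axis=0)
        hi = np.quantile(sims, 1 - alpha, axis=0)
    else:
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, fit.cov, D), 0.0))
        lo, hi = d - z * se, d + z * se
    # degenerate-input guard: on noiseless data the posterior scale
    # collapses and float-level wiggle would count as "significant"
    tol = 1e-8 * max(1.0, float(np.max(np.abs(fit.coef))))
    return DerivativeSeries(
        grid=grid,
        deriv=d,
        ci_lower=lo,
        ci_upper=hi,
        significant=(lo > tol) | (hi < -tol),
    )


def find_turning_points(derivs: DerivativeSeries) -> list[TurningPoint]:
    """Sign changes of the derivative point estimate, with significance.

    One turning point per adjacent grid pair whose derivative signs
    oppose; flagged significant when the derivative CI excludes zero on
    at least one flank of the change. Exact zeros carry the preceding
    sign forward, so a touch-and-go zero is not double counted.
    """
    d = np.asarray(derivs.deriv)
    if len(d) < 2:
        raise ValueError("derivative grid needs at least 2 points")
    signs = np.sign(d)
    for i in range(1, len(signs)):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    out = []
    for i in range(len(d) - 1):
        if signs[i] != 0 and signs[i + 1] != 0 and signs[i] != signs[i + 1]:
            direction = (
                "positive_to_negative" if signs[i] > 0 else "negative_to_positive"
            )
            sig = bool(derivs.significant[i] or derivs.significant[i + 1])
            out.append(
                TurningPoint(
                    interval=(float(derivs.grid[i]), float(derivs.grid[i + 1])),
                    direction=direction,
                    significant=sig,
                )
            )
    return out


def significant_periods(derivs: DerivativeSeries) -> list[dict]:
    """Maximal grid runs where the derivative CI excludes zero.

    Each period carries its start/end year and the derivative sign
    ("positive" for significant increase, "negative" for decline).
    """
    out = []
    sig = np.asarray(derivs.significant)
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            sign = "positive" if derivs.deriv[i] > 0 else "negative"
            while (
                j + 1 < len(sig)
                and sig[j + 1]
                and (derivs.deriv[j + 1] > 0) == (sign == "positive")
            ):
                j += 1
            out.append(
                {
                    "start_year": float(derivs.grid[i]),
                    "end_year": float(derivs.grid[j]),
                    "sign": sign,
                }
            )
            i = j + 1
        else:
            i += 1
    return out


def trend_frame(fit: TrendFit, derivs: DerivativeSeries) -> pd.DataFrame:
    """Fitted curve and derivative series as one tidy table per grid year."""
    if len(fit.grid) != len(derivs.grid) or not np.allclose(fit.grid, derivs.grid):
        raise ValueError("fit and derivative grids differ")
    return pd.DataFrame(
        {
            "colony": fit.colony,
            "year": fit.grid,
            "fit": fit.fitted,
            "ci_lower": fit.ci_lower,
            "ci_upper": fit.ci_upper,
            "derivative": derivs.deriv,
            "d_ci_lower": derivs.ci_lower,
            "d_ci_upper": derivs.ci_upper,
            "significant": derivs.significant,
        }
    )
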