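"""Bivariate allometric line fitting: OLS, standardized major axis, calibration.

Allometric scaling is analysed on log10-transformed trait values, so a slope
of 1 is isometry (proportional scaling) and slopes below 1 are hypoallometry.
Three line-fitting conventions are provided because they answer different
questions: OLS predicts y from x, SMA summarizes the bivariate major axis
(|slope| = sd(y)/sd(x), appropriate when both variables carry error), and
PGLS (in :mod:`frogeye.pgls`) additionally corrects for phylogeny.

The SMA slope test against a hypothesized value b0 uses the standard
correlation-of-axes statistic: under H0 the residual axis ``y - b0 x`` and
fitted axis ``y + b0 x`` are uncorrelated, and ``F = r^2 (n-2)/(1-r^2)`` with
(1, n-2) df.

The robust SMA variant replaces sample means/variances by Huber M-estimates
(tuning constant 1.345, IRLS to 1e-8, max 100 iterations), down-weighting
extreme points in either variable before taking the sd ratio.

The eye-diameter to axial-length calibration is a plain OLS fit on raw mm
pairs from fresh specimens; its transform is applied to species-mean eye
diameters to predict axial lengths where eyes cannot be dissected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pgls import design_matrix, profile_lambda
from .phylo import Phylogeny, phylo_covariance

logger = logging.getLogger(__name__)

__all__ = [
    "OLSFit",
    "SMAFit",
    "CalibrationTransform",
    "CladeDataset",
    "ols_fit",
    "sma_fit",
    "isometry_test",
    "ed_to_al_calibration",
    "batch_clade_fits",
]

HUBER_C = 1.345
HUBER_TOL = 1e-8
HUBER_MAX_ITER = 100


@dataclass
class OLSFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    t: float
    df: int
    r_squared: float
    F: float
    p: float
    n: int
    residuals: np.ndarray = field(repr=False)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def ols_fit(x: Iterable[float], y: Iterable[float]) -> OLSFit:
    """Simple linear regression with the standard diagnostics."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 cases, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    if np.var(y) == 0:
        # degenerate but well-defined: flat line through the constant
        return OLSFit(
            slope=0.0, intercept=float(y[0]), slope_se=0.0, intercept_se=0.0,
            t=0.0, df=n - 2, r_squared=0.0, F=0.0, p=1.0, n=n,
            residuals=np.zeros(n),
        )
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    df = n - 2
    # guard against a perfectly constant y, where linregress returns r = 0
    r2 = float(res.rvalue**2)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return OLSFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        t=float(t),
        df=df,
        r_squared=r2,
        F=float(t**2),
        p=float(res.pvalue),
        n=n,
        residuals=resid,
    )


def _huber_location_scale(v: np.ndarray, c: float = HUBER_C) -> tuple[float, float, np.ndarray]:
    """Huber M-estimates of location and scale with the final weights."""
    mu = float(np.median(v))
    s = float(stats.median_abs_deviation(v, scale="normal"))
    if s == 0:
        s = float(np.std(v)) or 1.0
    w = np.ones_like(v)
    for _ in range(HUBER_MAX_ITER):
        z = (v - mu) / s
        w = np.where(np.abs(z) <= c, 1.0, c / np.maximum(np.abs(z), 1e-300))
        mu_new = float(np.sum(w * v) / np.sum(w))
        s_new = float(np.sqrt(np.sum(w * (v - mu_new) ** 2) / np.sum(w)))
        if s_new == 0:
            mu, s = mu_new, s
            break
        if max(abs(mu_new - mu), abs(s_new - s)) < HUBER_TOL:
            mu, s = mu_new, s_new
            break
        mu, s = mu_new, s_new
    return mu, s, w


@dataclass
class SMAFit:
    """Standardized major axis fit. ``|slope| = sd(y)/sd(x)``, signed by r."""

    slope: float
    intercept: float
    ci: tuple[float, float]
    n: int
    r: float
    method: str  # "least-squares" | "huber-m"
    isometry_F: float
    isometry_p: float
    _x: np.ndarray = field(repr=False)
    _y: np.ndarray = field(repr=False)


def sma_fit(x: Iterable[float], y: Iterable[float], robust: bool = False) -> SMAFit:
    """Standardized major axis line through (x, y).

    Least-squares SMA: slope = sign(r) sd(y)/sd(x), intercept through the
    means. With ``robust=True`` locations and scales come from Huber
    M-estimation, with the correlation sign taken from the jointly
    down-weighted data. The slope CI is the standard F-based interval
    (alpha = 0.05); the isometry test (slope = 1) is pre-computed.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 cases, got {n}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0.0:
        raise ValueError("correlation is exactly 0; SMA slope sign undefined")
    if robust:
        mx, sx, wx = _huber_location_scale(x)
        my, sy, wy = _huber_location_scale(y)
        w = np.minimum(wx, wy)
        cov_w = float(np.sum(w * (x - mx) * (y - my)) / np.sum(w))
        sign = np.sign(cov_w) or 1.0
        slope = sign * sy / sx
        intercept = my - slope * mx
        method = "huber-m"
    else:
        sx = float(np.std(x, ddof=1))
        sy = float(np.std(y, ddof=1))
        slope = float(np.sign(r) * sy / sx)
        intercept = float(np.mean(y) - slope * np.mean(x))
        method = "least-squares"

    # F-based CI on the slope (standard SMA interval)
    df = n - 2
    Fcrit = stats.f.ppf(0.95, 1, df)
    B = Fcrit * (1.0 - r**2) / df
    lo = slope * (np.sqrt(B + 1.0) - np.sqrt(B))
    hi = slope * (np.sqrt(B + 1.0) + np.sqrt(B))
    ci = (float(min(lo, hi)), float(max(lo, hi)))

    F1, p1 = _sma_slope_test(x, y, slope_h0=1.0)
    return SMAFit(
        slope=slope, intercept=intercept, ci=ci, n=n, r=r, method=method,
        isometry_F=F1, isometry_p=p1, _x=x, _y=y,
    )


def _sma_slope_test(x: np.ndarray, y: np.ndarray, slope_h0: float) -> tuple[float, float]:
    n = x.size
    resid_axis = y - slope_h0 * x
    fitted_axis = y + slope_h0 * x
    if np.var(resid_axis) == 0 or np.var(fitted_axis) == 0:
        return 0.0, 1.0
    r_rf = float(np.corrcoef(resid_axis, fitted_axis)[0, 1])
    df = n - 2
    F = r_rf**2 * df / max(1.0 - r_rf**2, 1e-300)
    p = float(stats.f.sf(F, 1, df))
    return float(F), p


def isometry_test(fit: SMAFit, b0: float = 1.0) -> tuple[float, float]:
    """Test H0: |SMA slope| = b0 via the residual/fitted-axis correlation.

    Returns ``(F, p)`` with (1, n-2) df. ``b0`` is applied with the sign of
    the fitted slope.
    """
    if fit.n < 4:
        raise ValueError("isometry test needs at least 4 cases")
    b0_signed = float(np.sign(fit.slope) * abs(b0))
    return _sma_slope_test(fit._x, fit._y, b0_signed)


@dataclass
class CalibrationTransform:
    """Linear measurement calibration, e.g. external ED -> dissected AL (mm)."""

    intercept: float
    slope: float
    fit: OLSFit

    def apply(self, values) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(values, dtype=float)


def ed_to_al_calibration(ed_mm: Iterable[float], al_mm: Iterable[float]) -> CalibrationTransform:
    """Fit AL = a + b ED on raw mm pairs from fresh specimens."""
    fit = ols_fit(ed_mm, al_mm)
    logger.info(
        "ed_to_al_calibration: AL = %.4f + %.4f ED (R2 = %.3f, n = %d)",
        fit.intercept, fit.slope, fit.r_squared, fit.n,
    )
    return CalibrationTransform(intercept=fit.intercept, slope=fit.slope, fit=fit)


@dataclass
class CladeDataset:
    """One clade's species table (log10 columns), optional tree, comparisons.

    ``comparisons`` is a list of ``(response, predictor)`` column-name pairs,
    e.g. ``[("AL_log", "RM_log"), ("ED_log", "SVL_log")]``.
    """

    name: str
    data: pd.DataFrame  # indexed by species label
    tree: Optional[Phylogeny]
    comparisons: Sequence[tuple[str, str]]


def batch_clade_fits(datasets: Sequence[CladeDataset]) -> pd.DataFrame:
    """Per-clade scaling fits for cross-clade comparison.

    For each clade and comparison: PGLS (ML lambda) when a tree is supplied,
    and OLS always, after dropping species missing either variable and (for
    PGLS) intersecting with the tree tips. Failures are recorded per row and
    the batch continues.
    """
    rows: list[dict] = []
    for ds in datasets:
        for response, predictor in ds.comparisons:
            sub = ds.data[[response, predictor]].dropna()
            try:
                fit = ols_fit(sub[predictor], sub[response])
                rows.append({
                    "clade": ds.name, "response": response, "predictor": predictor,
                    "method": "OLS", "slope": fit.slope, "intercept": fit.intercept,
                    "r_squared": fit.r_squared, "lambda": np.nan, "n": fit.n,
                    "error": "",
                })
            except Exception as err:  # record and continue
                rows.append({
                    "clade": ds.name, "response": response, "predictor": predictor,
                    "method": "OLS", "slope": np.nan, "intercept": np.nan,
                    "r_squared": np.nan, "lambda": np.nan, "n": len(sub),
                    "error": str(err),
                })
            if ds.tree is None:
                continue
            try:
                common = [t for t in ds.tree.tips if t in sub.index]
                tree = ds.tree if len(common) == ds.tree.n_tips else None
                from .phylo import prune_to_taxa
                pruned = prune_to_taxa(ds.tree, common) if tree is None else ds.tree
                cov = phylo_covariance(pruned)
                aligned = sub.loc[cov.taxa]
                X = design_matrix(aligned, [predictor])
                pfit = profile_lambda(X, aligned[response], cov)
                rows.append({
                    "clade": ds.name, "response": response, "predictor": predictor,
                    "method": "PGLS", "slope": pfit.slope, "intercept": pfit.intercept,
                    "r_squared": pfit.r_squared, "lambda": pfit.lambda_,
                    "n": pfit.n, "error": "",
                })
            except Exception as err:
                rows.append({
                    "clade": ds.name, "response": response, "predictor": predictor,
                    "method": "PGLS", "slope": np.nan, "intercept": np.nan,
                    "r_squared": np.nan, "lambda": np.nan, "n": len(sub),
                    "error": str(err),
                })
    columns = ["clade", "response", "predictor", "method", "slope",
               "intercept", "r_squared", "lambda", "n", "error"]
    return pd.DataFrame(rows, columns=columns)
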