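"""Causal estimators for two-sample MR.

Each estimator consumes a :class:`~mrkit.sumstats.HarmonizedInstrumentSet`
and returns an :class:`MRResult`.  All slope/intercept inference uses the
two-sided normal reference; Egger-family results carry an intercept (the
average horizontal pleiotropic effect).

Weighting conventions (first-order / fixed-effect throughout):

* IVW: weighted mean of the Wald ratios alpha_j/gamma_j with weights
  w_j = gamma_j²/sigma_y_j²; equivalently WLS of alpha on gamma through
  the origin with weights 1/sigma_y_j².
* MR-Egger: WLS of alpha on gamma with a free intercept and weights
  1/sigma_y_j², after orienting every SNP so gamma_j >= 0.
* SIMEX-corrected Egger: simulation-extrapolation against the exposure
  measurement error sigma_x, quadratic extrapolation to lambda = -1.
* Weighted median: the 50% point of the weight-ordered Wald ratios,
  linearly interpolated; SE by parametric bootstrap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import HarmonizedInstrumentSet

__all__ = [
    "Method",
    "MRResult",
    "ivw",
    "egger",
    "egger_simex",
    "weighted_median",
    "DEFAULT_LAMBDA_GRID",
]

Z975 = float(stats.norm.ppf(0.975))
DEFAULT_LAMBDA_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)


class Method(str, enum.Enum):
    IVW = "IVW"
    EGGER = "MR-Egger"
    EGGER_SIMEX = "MR-Egger (SIMEX)"
    WEIGHTED_MEDIAN = "Weighted median"
    PRESSO = "MR-PRESSO"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class MRResult:
    """One method's causal estimate (slope in outcome units per exposure unit)."""

    method: Method
    slope: float
    slope_se: float
    slope_ci: tuple[float, float]
    slope_pval: float
    n_snps_used: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_ci: tuple[float, float] | None = None
    intercept_pval: float | None = None
    outliers_removed: list[str] = field(default_factory=list)
    seed: int | None = None

    def tsv_row(self) -> str:
        def fmt(x):
            return "" if x is None else (f"{x[0]!r},{x[1]!r}" if isinstance(x, tuple) else repr(x))

        cells = [self.method.value, repr(self.slope), repr(self.slope_se),
                 repr(self.slope_ci[0]), repr(self.slope_ci[1]), repr(self.slope_pval),
                 fmt(self.intercept), fmt(self.intercept_se), fmt(self.intercept_pval),
                 str(self.n_snps_used), ",".join(self.outliers_removed)]
        return "\t".join(cells)

    def to_dict(self) -> dict:
        return {
            "method": self.method.value,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "slope_ci": list(self.slope_ci),
            "slope_pval": self.slope_pval,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_ci": None if self.intercept_ci is None else list(self.intercept_ci),
            "intercept_pval": self.intercept_pval,
            "n_snps_used": self.n_snps_used,
            "outliers_removed": list(self.outliers_removed),
            "seed": self.seed,
        }


def _wald(est: float, se: float) -> tuple[tuple[float, float], float]:
    ci = (est - Z975 * se, est + Z975 * se)
    p = 1.0 if se == 0 and est == 0 else float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else 0.0
    return ci, p


def _check_gamma(hset: HarmonizedInstrumentSet) -> None:
    if np.any(hset.gamma_hat == 0):
        raise ValueError("zero exposure effect")


def ivw(hset: HarmonizedInstrumentSet) -> MRResult:
    """Inverse-variance-weighted estimate (fixed-effect, first-order weights)."""
    if len(hset) < 2:
        raise ValueError("insufficient instruments")
    _check_gamma(hset)
    w = hset.gamma_hat**2 / hset.sigma_y**2
    ratios = hset.alpha_hat / hset.gamma_hat
    slope = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    ci, p = _wald(slope, se)
    return MRResult(Method.IVW, slope, se, ci, p, n_snps_used=len(hset))


def _orient(hset: HarmonizedInstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Orient every SNP so the exposure effect is nonnegative."""
    sign = np.where(hset.gamma_hat < 0, -1.0, 1.0)
    return sign * hset.gamma_hat, sign * hset.alpha_hat


def _wls_line(g: np.ndarray, a: np.ndarray, w: np.ndarray):
    """Closed-form WLS of a on g with intercept.  Returns
    (intercept, slope, se_intercept, se_slope)."""
    s0 = np.sum(w)
    s1 = np.sum(w * g)
    s2 = np.sum(w * g * g)
    sy = np.sum(w * a)
    sgy = np.sum(w * g * a)
    det = s0 * s2 - s1 * s1
    if det <= 0 or not np.isfinite(det):
        raise ValueError("degenerate design")
    slope = (s0 * sgy - s1 * sy) / det
    intercept = (sy - slope * s1) / s0
    se_slope = np.sqrt(s0 / det)
    se_intercept = np.sqrt(s2 / det)
    return float(intercept), float(slope), float(se_intercept), float(se_slope)


def egger(hset: HarmonizedInstrumentSet) -> MRResult:
    """MR-Egger regression: WLS with free intercept after gamma orientation."""
    if len(hset) < 3:
        raise ValueError("insufficient instruments for Egger")
    g, a = _orient(hset)
    if np.allclose(g, g[0]):
        raise ValueError("degenerate design")
    w = 1.0 / hset.sigma_y**2
    b0, b1, se0, se1 = _wls_line(g, a, w)
    ci1, p1 = _wald(b1, se1)
    ci0, p0 = _wald(b0, se0)
    return MRResult(
        Method.EGGER, b1, se1, ci1, p1, n_snps_used=len(hset),
        intercept=b0, intercept_se=se0, intercept_ci=ci0, intercept_pval=p0,
    )


def _egger_batch(g: np.ndarray, a: np.ndarray, w: np.ndarray):
    """Vectorized Egger fits over the leading axis.

    ``g``/``a`` have shape (..., J); ``w`` broadcasts.  Applies the gamma
    orientation per fit.  Returns (intercept, slope, var_intercept,
    var_slope) arrays of shape (...,).
    """
    sign = np.where(g < 0, -1.0, 1.0)
    g = g * sign
    a = a * sign
    s0 = np.sum(w * np.ones_like(g), axis=-1)
    s1 = np.sum(w * g, axis=-1)
    s2 = np.sum(w * g * g, axis=-1)
    sy = np.sum(w * a, axis=-1)
    sgy = np.sum(w * g * a, axis=-1)
    det = s0 * s2 - s1 * s1
    slope = (s0 * sgy - s1 * sy) / det
    intercept = (sy - slope * s1) / s0
    return intercept, slope, s2 / det, s0 / det


def egger_simex(
    hset: HarmonizedInstrumentSet,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    b_reps: int = 1000,
    seed: int = 0,
) -> MRResult:
    """SIMEX-corrected MR-Egger.

    For each lambda > 0 the exposure effects are perturbed with extra
    noise of variance lambda * sigma_x², the Egger fit is averaged over
    ``b_reps`` perturbations, and a quadratic in lambda is extrapolated
    to lambda = -1 (the error-free state).  Standard errors extrapolate
    the per-lambda mean model-based SEs the same way (the simple
    extrapolation variant; approximate).  With sigma_x identically zero
    this reduces exactly to :func:`egger`.
    """
    if len(hset) < 3:
        raise ValueError("insufficient instruments for Egger")
    if b_reps < 100:
        raise ValueError("insufficient SIMEX replicates")
    if 0.0 not in lambda_grid:
        raise ValueError("lambda grid must include 0")
    naive = egger(hset)
    if np.all(hset.sigma_x == 0):
        res = MRResult(
            Method.EGGER_SIMEX, naive.slope, naive.slope_se, naive.slope_ci,
            naive.slope_pval, naive.n_snps_used,
            intercept=naive.intercept, intercept_se=naive.intercept_se,
            intercept_ci=naive.intercept_ci, intercept_pval=naive.intercept_pval,
            seed=seed,
        )
        return res

    rng = np.random.default_rng(seed)
    lams = np.asarray(sorted(lambda_grid), dtype=float)
    w = 1.0 / hset.sigma_y**2
    mean_b0 = np.empty_like(lams)
    mean_b1 = np.empty_like(lams)
    mean_se1 = np.empty_like(lams)
    mean_se0 = np.empty_like(lams)
    for i, lam in enumerate(lams):
        if lam == 0.0:
            mean_b0[i], mean_b1[i] = naive.intercept, naive.slope
            mean_se0[i], mean_se1[i] = naive.intercept_se, naive.slope_se
            continue
        z = rng.standard_normal((b_reps, len(hset)))
        g = hset.gamma_hat + np.sqrt(lam) * hset.sigma_x * z
        a = np.broadcast_to(hset.alpha_hat, g.shape)
        b0, b1, v0, v1 = _egger_batch(g, a, w)
        mean_b0[i], mean_b1[i] = b0.mean(), b1.mean()
        mean_se0[i] = np.sqrt(np.mean(v0))
        mean_se1[i] = np.sqrt(np.mean(v1))

    def extrapolate(y: np.ndarray) -> float:
        deg = 2 if len(lams) >= 3 else 1
        coef = np.polyfit(lams, y, deg)
        return float(np.polyval(coef, -1.0))

    slope = extrapolate(mean_b1)
    intercept = extrapolate(mean_b0)
    se1 = extrapolate(mean_se1)
    se0 = extrapolate(mean_se0)
    # extrapolated SEs can go nonpositive on pathological grids; fall back
    se1 = se1 if se1 > 0 else naive.slope_se
    se0 = se0 if se0 > 0 else naive.intercept_se
    ci1, p1 = _wald(slope, se1)
    ci0, p0 = _wald(intercept, se0)
    return MRResult(
        Method.EGGER_SIMEX, slope, se1, ci1, p1, n_snps_used=len(hset),
        intercept=intercept, intercept_se=se0, intercept_ci=ci0, intercept_pval=p0,
        seed=seed,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray,
                           snp_ids: list[str] | None = None) -> float:
    """Interpolated weighted median of ``ratios`` under ``weights``.

    Ties broken by a stable sort on (ratio, snp_id)."""
    if snp_ids is not None:
        order = np.lexsort((np.asarray(snp_ids), ratios))
    else:
        order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w)
    p = s - w / 2.0
    return float(np.interp(0.5, p, r))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted medians for (B, J) arrays."""
    order = np.argsort(ratios, axis=1, kind="stable")
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / np.sum(w, axis=1, keepdims=True)
    s = np.cumsum(w, axis=1)
    p = s - w / 2.0
    # vectorized np.interp at 0.5 per row
    idx = np.sum(p < 0.5, axis=1)  # first index with p >= 0.5
    b, j = ratios.shape
    out = np.empty(b)
    lo = np.clip(idx - 1, 0, j - 1)
    hi = np.clip(idx, 0, j - 1)
    rows = np.arange(b)
    p_lo, p_hi = p[rows, lo], p[rows, hi]
    r_lo, r_hi = r[rows, lo], r[rows, hi]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(p_hi > p_lo, (0.5 - p_lo) / (p_hi - p_lo), 0.0)
    out = r_lo + frac * (r_hi - r_lo)
    out[idx == 0] = r[idx == 0, 0]      # 0.5 below first midpoint
    out[idx == j] = r[idx == j, j - 1]  # 0.5 above last midpoint
    return out


def weighted_median(
    hset: HarmonizedInstrumentSet,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Weighted-median estimator; consistent with up to 50% invalid weight.

    Point estimate is the interpolated 50% point of the weight-ordered
    Wald ratios (weights gamma²/sigma_y²).  The SE is the standard
    deviation of the estimator over ``n_boot`` parametric bootstrap draws
    of (gamma_hat, alpha_hat) from their sampling distributions.
    """
    if len(hset) < 3:
        raise ValueError("insufficient instruments")
    _check_gamma(hset)
    ratios = hset.alpha_hat / hset.gamma_hat
    weights = hset.gamma_hat**2 / hset.sigma_y**2
    est = _weighted_median_point(ratios, weights, hset.snp_ids)

    rng = np.random.default_rng(seed)
    g = hset.gamma_hat + hset.sigma_x * rng.standard_normal((n_boot, len(hset)))
    a = hset.alpha_hat + hset.sigma_y * rng.standard_normal((n_boot, len(hset)))
    g = np.where(g == 0, np.finfo(float).tiny, g)
    boot = _weighted_median_rows(a / g, g**2 / hset.sigma_y**2)
    se = float(np.std(boot, ddof=1))
    ci, p = _wald(est, se)
    return MRResult(Method.WEIGHTED_MEDIAN, est, se, ci, p,
                    n_snps_used=len(hset), seed=seed)
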