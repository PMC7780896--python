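"""MR-PRESSO: global pleiotropy test, outlier test, and distortion test.

The residual sum of squares (RSS) of the observed SNP-outcome effects
about their leave-one-out IVW predictions is compared against its
parametric-simulation null distribution (global test).  Per-SNP residual
terms give outlier p-values (Bonferroni-corrected); the causal estimate
is re-fit by IVW on the non-outlier subset, and the distortion test asks
whether dropping the flagged SNPs moved the estimate more than dropping
an equally sized random subset would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .estimators import Method, MRResult, ivw
from .sumstats import HarmonizedInstrumentSet

__all__ = ["PressoReport", "presso"]


@dataclass
class PressoReport:
    global_rss: float
    global_pval: float
    per_snp_pvals: dict[str, float]
    outliers: list[str]
    raw_result: MRResult
    corrected_result: MRResult | None
    distortion_pval: float | None
    n_sim: int
    seed: int
    dropped_for_correction: list[str] = field(default_factory=list)

    @property
    def has_outliers(self) -> bool:
        return bool(self.outliers)

    def to_json(self) -> str:
        return json.dumps({
            "global_rss": self.global_rss,
            "global_pval": self.global_pval,
            "per_snp_pvals": self.per_snp_pvals,
            "outliers": self.outliers,
            "raw": self.raw_result.to_dict(),
            "corrected": None if self.corrected_result is None else self.corrected_result.to_dict(),
            "distortion_pval": self.distortion_pval,
            "n_sim": self.n_sim,
            "seed": self.seed,
        })

    def corrected_tsv_row(self) -> str | None:
        """Outlier-corrected estimate as a standard result row, labeled
        'MR-PRESSO (O-C)'; None when no outliers were flagged."""
        if self.corrected_result is None:
            return None
        return "MR-PRESSO (O-C)\t" + "\t".join(
            self.corrected_result.tsv_row().split("\t")[1:]
        )


def _loo_ivw_slopes(g: np.ndarray, a: np.ndarray, sy2: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized over the trailing SNP axis.

    Inputs may be (J,) or (B, J); output matches the input shape.
    """
    w = g**2 / sy2
    wb = g * a / sy2  # w * (a/g)
    sw = np.sum(w, axis=-1, keepdims=True)
    swb = np.sum(wb, axis=-1, keepdims=True)
    return (swb - wb) / (sw - w)


def presso(
    hset: HarmonizedInstrumentSet,
    n_sim: int = 5000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoReport:
    """Run the three-part MR-PRESSO procedure.

    ``global_pval`` uses the add-one rule and therefore has resolution
    1/(n_sim+1).  Outliers are flagged at per-SNP p < outlier_alpha/J.
    """
    j = len(hset)
    if j < 4:
        raise ValueError("insufficient instruments for PRESSO")
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    if np.any(hset.gamma_hat == 0):
        raise ValueError("zero exposure effect")

    rng = np.random.default_rng(seed)
    g, a = hset.gamma_hat, hset.alpha_hat
    sx, sy = hset.sigma_x, hset.sigma_y
    sy2 = sy**2

    beta_loo = _loo_ivw_slopes(g, a, sy2)
    terms = (a - beta_loo * g) ** 2 / sy2
    rss = float(np.sum(terms))

    # parametric null: expected outcome effects from the LOO slopes
    g_sim = g + sx * rng.standard_normal((n_sim, j))
    a_sim = beta_loo * g + sy * rng.standard_normal((n_sim, j))
    g_sim = np.where(g_sim == 0, np.finfo(float).tiny, g_sim)
    beta_loo_sim = _loo_ivw_slopes(g_sim, a_sim, sy2)
    terms_sim = (a_sim - beta_loo_sim * g_sim) ** 2 / sy2
    rss_sim = np.sum(terms_sim, axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss)) / (n_sim + 1))
    per_snp = (1 + np.sum(terms_sim >= terms, axis=0)) / (n_sim + 1)
    per_snp_pvals = {s: float(p) for s, p in zip(hset.snp_ids, per_snp)}
    outlier_mask = per_snp < outlier_alpha / j
    outliers = [s for s, o in zip(hset.snp_ids, outlier_mask) if o]
    if len(outliers) == j:
        raise ValueError("no instruments remain after outlier removal")

    raw = ivw(hset)
    raw.method = Method.PRESSO

    corrected = None
    distortion_pval = None
    if outliers:
        keep = ~outlier_mask
        sub = hset.subset(keep, reason="PRESSO outlier")
        corrected = ivw(sub)
        corrected.method = Method.PRESSO
        corrected.outliers_removed = list(outliers)
        corrected.seed = seed

        # distortion: compare the observed shift against shifts from
        # dropping random subsets of the same size
        k = len(outliers)
        d_obs = (raw.slope - corrected.slope) / abs(corrected.slope) if corrected.slope != 0 else np.inf
        w_all = g**2 / sy2
        wb_all = g * a / sy2
        sw, swb = np.sum(w_all), np.sum(wb_all)
        drop_idx = np.argsort(rng.random((n_sim, j)), axis=1)[:, :k]
        slope_b = (swb - np.sum(wb_all[drop_idx], axis=1)) / (sw - np.sum(w_all[drop_idx], axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            d_null = np.where(slope_b != 0, (raw.slope - slope_b) / np.abs(slope_b), np.inf)
        distortion_pval = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))

    return PressoReport(
        global_rss=rss,
        global_pval=global_pval,
        per_snp_pvals=per_snp_pvals,
        outliers=outliers,
        raw_result=raw,
        corrected_result=corrected,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )
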