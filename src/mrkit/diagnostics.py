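"""Instrument-quality diagnostics for two-sample MR.

Four statistics route the downstream analysis:

* mean F — average per-SNP instrument strength (gamma_hat/sigma_x)^2;
  mean F <= 10 flags weak-instrument bias (IV1 at risk).
* I²_GX — heterogeneity of the SNP-exposure effects relative to their
  sampling error; values below 0.90 flag violation of the NOME
  (no-measurement-error) assumption and hence regression dilution of the
  MR-Egger slope.
* Cochran's Q — heterogeneity of the per-SNP Wald ratios about the IVW
  estimate (first-order weights), chi-square with J-1 df under the null.
* Rücker's Q′ — residual heterogeneity about the MR-Egger fit, chi-square
  with J-2 df; Q′ << Q indicates directional pleiotropy absorbed by the
  Egger intercept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .sumstats import HarmonizedInstrumentSet

__all__ = ["DiagnosticsReport", "mean_f", "i2_gx", "heterogeneity", "diagnose"]

WEAK_F_THRESHOLD = 10.0
NOME_I2_THRESHOLD = 0.90
SIGNIFICANCE = 0.05


@dataclass
class DiagnosticsReport:
    j_snps: int
    mean_f: float
    i2_gx: float
    q_stat: float
    q_pval: float
    q_prime_stat: float
    q_prime_pval: float
    presso_global_pval: float | None = None

    @property
    def weak_instruments(self) -> bool:
        return self.mean_f <= WEAK_F_THRESHOLD

    @property
    def nome_violated(self) -> bool:
        # equality counts as satisfied
        return self.i2_gx < NOME_I2_THRESHOLD

    @property
    def q_sig(self) -> bool:
        return self.q_pval < SIGNIFICANCE

    @property
    def q_prime_sig(self) -> bool:
        return self.q_prime_pval < SIGNIFICANCE

    @property
    def rss_sig(self) -> bool | None:
        if self.presso_global_pval is None:
            return None
        return self.presso_global_pval < SIGNIFICANCE

    def flags(self) -> dict:
        return {
            "weak_instruments": self.weak_instruments,
            "nome_violated": self.nome_violated,
            "q_sig": self.q_sig,
            "q_prime_sig": self.q_prime_sig,
            "rss_sig": self.rss_sig,
        }

    def to_json(self) -> str:
        d = asdict(self)
        d.update(self.flags())
        return json.dumps(d)

    def tsv_row(self) -> str:
        fields = [self.j_snps, self.mean_f, self.i2_gx, self.q_stat, self.q_pval,
                  self.q_prime_stat, self.q_prime_pval,
                  "" if self.presso_global_pval is None else self.presso_global_pval]
        return "\t".join(str(f) for f in fields)


def mean_f(hset: HarmonizedInstrumentSet) -> float:
    """Mean per-SNP F statistic, (1/J) sum_j (gamma_hat_j / sigma_x_j)^2."""
    if len(hset) < 1:
        raise ValueError("empty instrument set")
    return float(np.mean((hset.gamma_hat / hset.sigma_x) ** 2))


def i2_gx(hset: HarmonizedInstrumentSet) -> float:
    """I² statistic for the SNP-exposure effects (NOME violation gauge).

    Computes the weighted heterogeneity Q_GX of gamma_hat with weights
    1/sigma_x², then (Q_GX - (J-1)) / Q_GX clamped to [0, 1].
    """
    j = len(hset)
    if j < 2:
        raise ValueError("I2 undefined for fewer than 2 instruments")
    w = 1.0 / hset.sigma_x**2
    gbar = np.sum(w * hset.gamma_hat) / np.sum(w)
    q_gx = float(np.sum(w * (hset.gamma_hat - gbar) ** 2))
    if q_gx == 0.0:
        return 0.0
    return float(min(1.0, max(0.0, (q_gx - (j - 1)) / q_gx)))


def heterogeneity(hset: HarmonizedInstrumentSet) -> tuple[float, float, float, float]:
    """Cochran's Q about the IVW estimate and Rücker's Q′ about the Egger fit.

    Returns ``(q_stat, q_pval, q_prime_stat, q_prime_pval)``.  Q uses
    first-order Wald-ratio weights w_j = gamma_j²/sigma_y_j² with J-1 df;
    Q′ is the weighted residual sum of squares of the MR-Egger regression
    with J-2 df.
    """
    from .estimators import ivw, egger  # deferred: estimators imports this module's types

    j = len(hset)
    if j < 3:
        raise ValueError("heterogeneity requires at least 3 instruments")
    if np.any(hset.gamma_hat == 0):
        raise ValueError("zero exposure effect")
    ratios = hset.alpha_hat / hset.gamma_hat
    w = hset.gamma_hat**2 / hset.sigma_y**2
    b_ivw = ivw(hset).slope
    q = float(np.sum(w * (ratios - b_ivw) ** 2))
    q_p = float(stats.chi2.sf(q, j - 1))

    eg = egger(hset)
    sign = np.where(hset.gamma_hat < 0, -1.0, 1.0)
    g, a = sign * hset.gamma_hat, sign * hset.alpha_hat
    resid = a - eg.intercept - eg.slope * g
    q_prime = float(np.sum(resid**2 / hset.sigma_y**2))
    q_prime_p = float(stats.chi2.sf(q_prime, j - 2))
    return q, q_p, q_prime, q_prime_p


def diagnose(
    hset: HarmonizedInstrumentSet,
    presso_global_pval: float | None = None,
) -> DiagnosticsReport:
    """Assemble the full diagnostics report for one harmonized set."""
    q, qp, qprime, qprimep = heterogeneity(hset)
    return DiagnosticsReport(
        j_snps=len(hset),
        mean_f=mean_f(hset),
        i2_gx=i2_gx(hset),
        q_stat=q,
        q_pval=qp,
        q_prime_stat=qprime,
        q_prime_pval=qprimep,
        presso_global_pval=presso_global_pval,
    )
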