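"""Synthetic two-sample GWAS summary statistics.

Generates exposure (sample 1) and outcome (sample 2) association tables
under the standard two-sample generative model with a per-SNP confounder
link psi_j:

    gamma_hat_j = gamma_j + kx * psi_j + eps_Xj,   eps_Xj ~ N(0, sigma_Xj²)
    alpha_hat_j = alpha_j + ky * psi_j + beta * (gamma_j + kx * psi_j) + eps_Yj

where beta is the true causal effect, alpha_j the direct (pleiotropic)
effect on the outcome, and kx/ky the confounder loadings.  Every IV
assumption can be violated in a controlled way: pleiotropy (alpha_j law,
balanced or directional), InSIDE (correlation between alpha_j and
gamma_j), weak instruments (gamma vs sigma_X scales), and NOME (sigma_X
large relative to the spread of gamma).  A truth record retains every
latent quantity for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .sumstats import AssociationRecord

__all__ = ["GammaLaw", "SimulationConfig", "generate", "scenario",
           "outcome_records_from_truth", "write_truth", "SCENARIO_NAMES"]

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)


@dataclass(frozen=True)
class GammaLaw:
    """Law of the true SNP-exposure effects: |gamma_j| ~ Uniform(low, high),
    optionally with a random sign."""

    low: float = 0.05
    high: float = 0.3
    random_sign: bool = True


@dataclass(frozen=True)
class SimulationConfig:
    j_snps: int = 30
    beta: float = 0.0
    gamma_law: GammaLaw = field(default_factory=GammaLaw)
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    frac_invalid: float = 0.0
    inside_corr: float = 0.0
    confounder_kx: float = 0.0
    confounder_ky: float = 0.0
    psi_sd: float = 0.0
    sigma_x_range: tuple[float, float] = (0.003, 0.008)
    sigma_y_range: tuple[float, float] = (0.05, 0.15)
    n_exposure: int = 133_010
    n_outcome: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.45)
    palindrome_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.j_snps < 1:
            raise ValueError("j_snps must be >= 1")
        for name in ("sigma_x_range", "sigma_y_range", "maf_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be an ordered nonnegative interval")
        if not (0.0 <= self.frac_invalid <= 1.0):
            raise ValueError("frac_invalid must lie in [0,1]")
        if not (-1.0 <= self.inside_corr <= 1.0):
            raise ValueError("inside_corr must lie in [-1,1]")


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def _records(
    ids, chrom, pos, ea, oa, eaf, beta, se, n
) -> list[AssociationRecord]:
    p = _two_sided_p(beta / se)
    return [
        AssociationRecord(ids[j], str(chrom[j]), int(pos[j]), ea[j], oa[j],
                          float(eaf[j]), float(beta[j]), float(se[j]),
                          float(p[j]), int(n))
        for j in range(len(ids))
    ]


def generate(cfg: SimulationConfig):
    """Draw one synthetic exposure/outcome table pair.

    Returns ``(exposure_records, outcome_records, truth)``; ``truth``
    holds every latent quantity (gamma, psi, direct effects, noise
    scales, the invalid-SNP mask, beta and the seed).
    """
    rng = np.random.default_rng(cfg.seed)
    j = cfg.j_snps

    mag = rng.uniform(cfg.gamma_law.low, cfg.gamma_law.high, size=j)
    sign = rng.choice([-1.0, 1.0], size=j) if cfg.gamma_law.random_sign else np.ones(j)
    gamma = mag * sign
    psi = cfg.psi_sd * rng.standard_normal(j) if cfg.psi_sd > 0 else np.zeros(j)

    n_invalid = int(round(cfg.frac_invalid * j))
    invalid = np.zeros(j, dtype=bool)
    if n_invalid:
        invalid[rng.choice(j, size=n_invalid, replace=False)] = True
    alpha_direct = np.zeros(j)
    if n_invalid and (cfg.pleiotropy_sd > 0 or cfg.pleiotropy_mean != 0):
        z = rng.standard_normal(n_invalid)
        rho = cfg.inside_corr
        if rho != 0 and n_invalid > 1 and np.std(gamma[invalid]) > 0:
            zg = (gamma[invalid] - np.mean(gamma[invalid])) / np.std(gamma[invalid])
            mix = rho * zg + np.sqrt(1.0 - rho**2) * z
        else:
            mix = z
        alpha_direct[invalid] = cfg.pleiotropy_mean + cfg.pleiotropy_sd * mix

    sigma_x = rng.uniform(*cfg.sigma_x_range, size=j)
    sigma_y = rng.uniform(*cfg.sigma_y_range, size=j)

    gamma_tot = gamma + cfg.confounder_kx * psi
    gamma_hat = gamma_tot + sigma_x * rng.standard_normal(j)
    alpha_hat = (alpha_direct + cfg.confounder_ky * psi + cfg.beta * gamma_tot
                 + sigma_y * rng.standard_normal(j))

    ids = [f"rs{cfg.seed % 1_000_000}{j_:04d}" for j_ in range(j)]
    chrom = [(j_ % 22) + 1 for j_ in range(j)]
    # 25 Mb spacing keeps same-chromosome SNPs outside a 10,000 kb window
    pos = [25_000_000 * (j_ // 22 + 1) + (j_ % 22) for j_ in range(j)]
    n_pal = int(round(cfg.palindrome_frac * j))
    pal = np.zeros(j, dtype=bool)
    if n_pal:
        pal[rng.choice(j, size=n_pal, replace=False)] = True
    ea, oa = [], []
    for j_ in range(j):
        pool = _PALINDROMIC_PAIRS if pal[j_] else _NONPALINDROMIC_PAIRS
        a, b = pool[rng.integers(len(pool))]
        ea.append(a)
        oa.append(b)
    eaf = rng.uniform(*cfg.maf_range, size=j)

    exposure = _records(ids, chrom, pos, ea, oa, eaf, gamma_hat, sigma_x, cfg.n_exposure)
    outcome = _records(ids, chrom, pos, ea, oa, eaf, alpha_hat, sigma_y, cfg.n_outcome)
    truth = {
        "seed": cfg.seed,
        "beta": cfg.beta,
        "snp_ids": ids,
        "chrom": [str(c) for c in chrom],
        "pos_bp": pos,
        "effect_allele": ea,
        "other_allele": oa,
        "eaf": eaf.tolist(),
        "gamma": gamma.tolist(),
        "gamma_total": gamma_tot.tolist(),
        "psi": psi.tolist(),
        "alpha_direct": alpha_direct.tolist(),
        "invalid": invalid.tolist(),
        "sigma_x": sigma_x.tolist(),
        "sigma_y": sigma_y.tolist(),
        "kx": cfg.confounder_kx,
        "ky": cfg.confounder_ky,
    }
    return exposure, outcome, truth


def outcome_records_from_truth(
    truth: dict,
    beta: float,
    seed: int,
    sigma_y_range: tuple[float, float] = (0.05, 0.15),
    n_outcome: int = 100_000,
) -> list[AssociationRecord]:
    """Draw a fresh outcome table for the latent SNP effects in ``truth``.

    Used to pair one exposure draw with several outcome traits (or a
    replication outcome) that share the same instruments but have their
    own causal effect ``beta`` and their own sampling noise.
    """
    rng = np.random.default_rng(seed)
    j = len(truth["snp_ids"])
    gamma_tot = np.asarray(truth["gamma_total"])
    alpha_direct = np.asarray(truth["alpha_direct"])
    psi = np.asarray(truth["psi"])
    sigma_y = rng.uniform(*sigma_y_range, size=j)
    alpha_hat = (alpha_direct + truth["ky"] * psi + beta * gamma_tot
                 + sigma_y * rng.standard_normal(j))
    return _records(truth["snp_ids"], truth["chrom"], truth["pos_bp"],
                    truth["effect_allele"], truth["other_allele"],
                    np.asarray(truth["eaf"]), alpha_hat, sigma_y, n_outcome)


def write_truth(truth: dict, path: str | Path) -> None:
    """Write the truth sidecar as JSON."""
    Path(path).write_text(json.dumps(truth, indent=1))


SCENARIO_NAMES = (
    "null", "valid_causal", "balanced_pleiotropy", "directional_pleiotropy",
    "inside_violated", "weak_instruments", "nome_violated", "outlier_contaminated",
)


def scenario(name: str, j_snps: int | None = None, seed: int = 0) -> SimulationConfig:
    """Documented presets, one per IV-assumption regime.

    * ``null`` — no causal effect, all assumptions satisfied.
    * ``valid_causal`` — beta = 0.2, all assumptions satisfied.
    * ``balanced_pleiotropy`` — direct effects on every SNP, mean zero.
    * ``directional_pleiotropy`` — direct effects with mean 0.05, InSIDE holds.
    * ``inside_violated`` — directional pleiotropy correlated with
      instrument strength (rho = 0.7).

    Sign-coherent (directional) regimes orient gamma positive: a nonzero
    mean direct effect is only meaningful relative to the
    exposure-raising allele, and with random gamma signs it would cancel
    in the Wald ratios instead of biasing them.
    * ``weak_instruments`` — mean F well below 10.
    * ``nome_violated`` — sigma_x scaled so I²_GX is about 0.6-0.8
      (positive-sign gamma law, so spread is small relative to error);
      true beta = 0.3 to make the Egger dilution visible.
    * ``outlier_contaminated`` — 10% of SNPs carry direct effects of
      about five outcome SEs.
    """
    base = SimulationConfig(seed=seed)
    presets = {
        "null": base,
        "valid_causal": replace(base, beta=0.2),
        "balanced_pleiotropy": replace(
            base, beta=0.2, frac_invalid=1.0, pleiotropy_mean=0.0, pleiotropy_sd=0.05),
        "directional_pleiotropy": replace(
            base, beta=0.2, frac_invalid=1.0, pleiotropy_mean=0.05,
            pleiotropy_sd=0.02, inside_corr=0.0,
            gamma_law=GammaLaw(random_sign=False)),
        "inside_violated": replace(
            base, beta=0.2, frac_invalid=1.0, pleiotropy_mean=0.05,
            pleiotropy_sd=0.05, inside_corr=0.7,
            gamma_law=GammaLaw(random_sign=False)),
        "weak_instruments": replace(
            base, gamma_law=GammaLaw(0.01, 0.05), sigma_x_range=(0.01, 0.02)),
        "nome_violated": replace(
            base, beta=0.3, gamma_law=GammaLaw(0.1, 0.3, random_sign=False),
            sigma_x_range=(0.034, 0.042), sigma_y_range=(0.008, 0.015)),
        "outlier_contaminated": replace(
            base, beta=0.2, j_snps=20, frac_invalid=0.1,
            pleiotropy_mean=0.5, pleiotropy_sd=0.01, sigma_y_range=(0.08, 0.12),
            gamma_law=GammaLaw(random_sign=False)),
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    cfg = presets[name]
    if j_snps is not None:
        cfg = replace(cfg, j_snps=j_snps)
    return cfg
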