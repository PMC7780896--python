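import numpy as np
import pytest

from mrkit.simulate import generate, scenario
from mrkit.sumstats import AssociationRecord, HarmonizedInstrumentSet, harmonize


def record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
           beta=0.1, se=0.01, pval=1e-9, n=10000) -> AssociationRecord:
    return AssociationRecord(snp_id, chrom, pos, ea, oa, eaf, beta, se, pval, n)


def make_hset(gamma, sigma_x, alpha, sigma_y) -> HarmonizedInstrumentSet:
    gamma = np.asarray(gamma, dtype=float)
    ids = [f"rs{i}" for i in range(len(gamma))]
    return HarmonizedInstrumentSet("X", "Y", ids, gamma,
                                   np.asarray(sigma_x, float),
                                   np.asarray(alpha, float),
                                   np.asarray(sigma_y, float))


def draw_hset(name: str, seed: int, j_snps: int | None = None) -> HarmonizedInstrumentSet:
    """One harmonized instrument set drawn from a named scenario."""
    exposure, outcome, _ = generate(scenario(name, j_snps=j_snps, seed=seed))
    return harmonize(exposure, outcome)


@pytest.fixture
def simple_hset() -> HarmonizedInstrumentSet:
    rng = np.random.default_rng(7)
    gamma = rng.uniform(0.1, 0.3, 6)
    return make_hset(gamma, rng.uniform(0.005, 0.01, 6),
                     0.4 * gamma + rng.normal(0, 0.02, 6),
                     rng.uniform(0.05, 0.1, 6))
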