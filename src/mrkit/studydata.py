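"""Synthetic instantiation of the glycemic-traits study design.

Builds a complete :class:`~mrkit.pipeline.StudyConfig` mirroring the
three-exposure (FPG-like 34 SNPs, 2h-PG-like 7, HbA1c-like 11) by
thirteen-outcome (6 cancer, 7 vascular) design, with replication outcome
sources for CAD and LDL cholesterol and true causal effects only for
FPG -> CAD and HbA1c -> LDL cholesterol.  Each exposure's instruments
are drawn once; every outcome trait re-draws its own outcome-sample
noise from the shared latent truth, so a given outcome source covers the
instruments of all three exposures.
"""

from __future__ import annotations

from dataclasses import replace

from .datasets import CANCER_OUTCOMES, VASCULAR_OUTCOMES
from .pipeline import OutcomeSpec, StudyConfig, derive_seed
from .simulate import SimulationConfig, generate, outcome_records_from_truth

__all__ = ["EXPOSURE_SIZES", "TRUE_EFFECTS", "synthetic_study"]

EXPOSURE_SIZES = {"FPG": 34, "2h-PG": 7, "HbA1c": 11}

#: nonzero true causal effects in the synthetic design
TRUE_EFFECTS = {("FPG", "CAD"): 0.21, ("HbA1c", "LDL cholesterol"): 0.23}

REPLICATED_OUTCOMES = ("CAD", "LDL cholesterol")


def synthetic_study(seed: int = 0, **config_overrides) -> StudyConfig:
    """Generate all sources for the 3 x 13 design and assemble the config."""
    truths = {}
    exposures = {}
    for name, j in EXPOSURE_SIZES.items():
        cfg = SimulationConfig(j_snps=j, seed=derive_seed(seed, "exposure", name))
        exp_records, _, truth = generate(cfg)
        exposures[name] = exp_records
        truths[name] = truth

    outcomes = {}
    for category, names in (("cancer", CANCER_OUTCOMES), ("vascular", VASCULAR_OUTCOMES)):
        for out_name in names:
            records = []
            for exp_name, truth in truths.items():
                beta = TRUE_EFFECTS.get((exp_name, out_name), 0.0)
                records += outcome_records_from_truth(
                    truth, beta, seed=derive_seed(seed, "outcome", out_name, exp_name))
            replication = None
            if out_name in REPLICATED_OUTCOMES:
                replication = []
                for exp_name, truth in truths.items():
                    beta = TRUE_EFFECTS.get((exp_name, out_name), 0.0)
                    replication += outcome_records_from_truth(
                        truth, beta,
                        seed=derive_seed(seed, "replication", out_name, exp_name))
            outcomes[out_name] = OutcomeSpec(records, category, replication)

    return StudyConfig(exposures=exposures, outcomes=outcomes, seed=seed,
                       **config_overrides)
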