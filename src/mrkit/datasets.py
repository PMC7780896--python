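"""Bundled reference data for validating the method selector.

``glycemic_assumption_checks`` returns the published assumption-check
summary for a three-exposure (FPG, 2h-PG, HbA1c) by thirteen-outcome MR
study of type-2-diabetes-related glycemic traits against cancers and
vascular disease: per exposure-outcome pair the instrument count, mean F
statistic, I²_GX (percent), and p-values for Cochran's Q, Rücker's Q′
and the MR-PRESSO global (RSS) test, together with the MR method chosen
in the source analysis.  Cells reported only as "<0.001" are encoded as
1e-4.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["glycemic_assumption_checks", "CANCER_OUTCOMES", "VASCULAR_OUTCOMES"]

CANCER_OUTCOMES = (
    "Breast cancer", "Lung cancer", "SC lung cancer",
    "Ovarian cancer", "Pancreatic cancer", "Thyroid cancer",
)
VASCULAR_OUTCOMES = (
    "CAD", "CKD", "HDL cholesterol", "LDL cholesterol",
    "Stroke", "Cardioembolic stroke", "Small-vessel stroke",
)

# exposure, outcome, category, n_snps, mean_f, i2_gx_pct, q_pval, q_prime_pval,
# presso_global_pval, reported_method
_TSV = """\
exposure	outcome	category	n_snps	mean_f	i2_gx_pct	q_pval	q_prime_pval	presso_global_pval	reported_method
FPG	Breast cancer	cancer	34	130.5	96.8	0.0001	0.0001	0.0001	MR-PRESSO
2h-PG	Breast cancer	cancer	7	43.5	29.8	0.0001	0.019	0.023	MR-Egger (SIMEX)
HbA1c	Breast cancer	cancer	11	77.6	92.2	0.110	0.249	0.371	IVW
FPG	Lung cancer	cancer	33	133.0	97.3	0.182	0.183	0.211	IVW
2h-PG	Lung cancer	cancer	7	43.5	36.2	0.322	0.397	0.258	IVW
HbA1c	Lung cancer	cancer	11	77.6	87.6	0.021	0.063	0.089	IVW
FPG	SC lung cancer	cancer	33	43.5	40.1	0.599	0.553	0.477	MR-Egger (SIMEX)
2h-PG	SC lung cancer	cancer	7	43.5	40.1	0.875	0.786	0.913	IVW
HbA1c	SC lung cancer	cancer	11	77.6	87.9	0.198	0.154	0.216	IVW
FPG	Ovarian cancer	cancer	33	133.5	97.4	0.530	0.490	0.412	IVW
2h-PG	Ovarian cancer	cancer	7	43.5	28.1	0.323	0.224	0.362	IVW
HbA1c	Ovarian cancer	cancer	11	77.6	87.8	0.243	0.334	0.298	IVW
FPG	Pancreatic cancer	cancer	25	111.7	96.4	0.138	0.122	0.199	IVW
2h-PG	Pancreatic cancer	cancer	6	45.0	31.8	0.710	0.594	0.642	IVW
HbA1c	Pancreatic cancer	cancer	8	82.1	90.9	0.239	0.186	0.214	IVW
FPG	Thyroid cancer	cancer	27	144.9	97.9	0.183	0.248	0.275	IVW
2h-PG	Thyroid cancer	cancer	5	47.4	21.9	0.434	0.703	0.621	IVW
HbA1c	Thyroid cancer	cancer	9	81.7	91.2	0.882	0.899	0.885	IVW
FPG	CAD	vascular	34	130.5	97.3	0.0001	0.0001	0.0001	MR-PRESSO
2h-PG	CAD	vascular	7	43.5	23.0	0.0001	0.0001	0.0001	MR-Egger (SIMEX)
HbA1c	CAD	vascular	11	77.6	88.0	0.002	0.014	0.018	IVW
FPG	CKD	vascular	32	135.8	97.4	0.106	0.114	0.151	IVW
2h-PG	CKD	vascular	7	43.5	29.1	0.482	0.451	0.395	IVW
HbA1c	CKD	vascular	10	82.1	86.5	0.632	0.548	0.421	IVW
FPG	HDL cholesterol	vascular	34	130.5	97.3	0.0001	0.0001	0.0001	MR-PRESSO
2h-PG	HDL cholesterol	vascular	7	43.5	2.4	0.0001	0.0001	0.0001	MR-Egger (SIMEX)
HbA1c	HDL cholesterol	vascular	11	77.6	90.9	0.545	0.589	0.436	IVW
FPG	LDL cholesterol	vascular	34	130.8	97.2	0.0001	0.0001	0.0001	MR-PRESSO
2h-PG	LDL cholesterol	vascular	7	43.5	5.7	0.0001	0.0001	0.0001	MR-Egger (SIMEX)
HbA1c	LDL cholesterol	vascular	11	77.6	91.1	0.0001	0.0001	0.0001	MR-PRESSO
FPG	Stroke	vascular	34	130.5	97.3	0.0001	0.0001	0.0001	MR-PRESSO
2h-PG	Stroke	vascular	7	43.5	39.9	0.069	0.051	0.067	IVW
HbA1c	Stroke	vascular	11	77.6	86.0	0.075	0.084	0.092	IVW
FPG	Cardioembolic stroke	vascular	34	130.5	97.4	0.498	0.649	0.557	IVW
2h-PG	Cardioembolic stroke	vascular	7	43.4	35.2	0.733	0.611	0.694	IVW
HbA1c	Cardioembolic stroke	vascular	11	77.6	88.7	0.255	0.247	0.275	IVW
FPG	Small-vessel stroke	vascular	32	135.8	97.6	0.038	0.130	0.199	MR-Egger
2h-PG	Small-vessel stroke	vascular	7	43.5	55.6	0.675	0.636	0.645	IVW
HbA1c	Small-vessel stroke	vascular	10	76.88	86.6	0.556	0.522	0.512	IVW
"""


def glycemic_assumption_checks() -> pd.DataFrame:
    """Return the bundled 39-row assumption-check table as a DataFrame."""
    return pd.read_csv(io.StringIO(_TSV), sep="\t")
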