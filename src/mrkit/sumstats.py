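"""GWAS summary-statistic I/O, LD clumping, and allele harmonization.

Two-sample MR works from per-SNP association tables: one for the exposure
(sample 1) and one for the outcome (sample 2).  Before any causal estimate
can be formed the two tables must describe the same variants on the same
effect-allele frame.  This module reads the tab-delimited summary format,
selects approximately independent instruments by greedy p-value clumping
under an externally supplied LD (r²) table, and harmonizes exposure and
outcome effects, resolving palindromic (A/T, C/G) variants by allele
frequency where that is unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AssociationRecord",
    "HarmonizedInstrumentSet",
    "SumstatsError",
    "read_sumstats",
    "write_sumstats",
    "read_r2_table",
    "clump",
    "harmonize",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names of the tab-delimited dialect
STANDARD_COLUMNS = ("SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N")


class SumstatsError(ValueError):
    """Raised for configuration-level problems (missing columns, no usable SNPs)."""


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's summary association with one trait.

    ``beta`` is the effect per copy of ``effect_allele`` in trait units
    (e.g. logOR for binary outcomes, mg/dL or SD for continuous ones).
    """

    snp_id: str
    chrom: str
    pos_bp: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self):
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise ValueError(f"non-SNP or multi-allelic alleles {ea}/{oa}")
        if ea == oa:
            raise ValueError("effect and other allele identical")
        if not (self.se > 0):
            raise ValueError("nonpositive SE")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError("EAF outside (0,1)")
        if not (0.0 <= self.pval <= 1.0):
            raise ValueError("p-value outside [0,1]")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class HarmonizedInstrumentSet:
    """Aligned per-SNP exposure/outcome effect pairs for one analysis.

    Vectors follow the usual two-sample notation: ``gamma_hat`` are the
    SNP-exposure effects with SEs ``sigma_x`` (sample 1); ``alpha_hat``
    are the SNP-outcome effects with SEs ``sigma_y`` (sample 2), after
    alignment to the exposure effect allele.
    """

    exposure_name: str
    outcome_name: str
    snp_ids: list[str]
    gamma_hat: np.ndarray
    sigma_x: np.ndarray
    alpha_hat: np.ndarray
    sigma_y: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        self.sigma_x = np.asarray(self.sigma_x, dtype=float)
        self.alpha_hat = np.asarray(self.alpha_hat, dtype=float)
        self.sigma_y = np.asarray(self.sigma_y, dtype=float)
        j = len(self.snp_ids)
        for name in ("gamma_hat", "sigma_x", "alpha_hat", "sigma_y"):
            if len(getattr(self, name)) != j:
                raise ValueError(f"{name} length != number of SNP ids")
        if len(set(self.snp_ids)) != j:
            raise ValueError("duplicate SNP ids")
        if np.any(self.sigma_x <= 0) or np.any(self.sigma_y <= 0):
            raise ValueError("nonpositive SE in harmonized set")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[bool] | np.ndarray, reason: str = "removed") -> "HarmonizedInstrumentSet":
        keep = np.asarray(keep, dtype=bool)
        ids = [s for s, k in zip(self.snp_ids, keep) if k]
        dropped = list(self.dropped) + [(s, reason) for s, k in zip(self.snp_ids, keep) if not k]
        return HarmonizedInstrumentSet(
            self.exposure_name, self.outcome_name, ids,
            self.gamma_hat[keep], self.sigma_x[keep],
            self.alpha_hat[keep], self.sigma_y[keep], dropped,
        )


def _build_column_map(header: Sequence[str], column_map: Mapping[str, str] | None) -> dict[str, int]:
    """Map canonical column names to indices in ``header``."""
    names = {c: c for c in STANDARD_COLUMNS}
    if column_map:
        names.update({k.upper(): v for k, v in column_map.items()})
    index = {}
    lookup = {h.strip(): i for i, h in enumerate(header)}
    for canonical, actual in names.items():
        if actual in lookup:
            index[canonical] = lookup[actual]
    mandatory = ("SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "P")
    missing = [c for c in mandatory if c not in index]
    if missing:
        raise SumstatsError(f"missing mandatory column(s): {', '.join(missing)}")
    return index


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[AssociationRecord], list[tuple[int, str]]]:
    """Read a tab-delimited summary-statistic table.

    Returns ``(records, rejected)`` where ``rejected`` lists
    ``(line_number, reason)`` for every data row that failed the record
    invariants (nonpositive SE, indel alleles, unparseable numerics, ...).
    Alleles are uppercased on read.  A missing mandatory column raises
    :class:`SumstatsError`.
    """
    path = Path(path)
    records: list[AssociationRecord] = []
    rejected: list[tuple[int, str]] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        index = _build_column_map(header, column_map)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                records.append(_parse_row(fields, index))
            except (ValueError, IndexError) as exc:
                rejected.append((lineno, str(exc)))
    return records, rejected


def _parse_row(fields: Sequence[str], index: Mapping[str, int]) -> AssociationRecord:
    def get(col, default=None):
        if col not in index:
            return default
        v = fields[index[col]].strip()
        return v if v not in ("", "NA", "nan", ".") else default

    eaf_raw = get("EAF")
    n_raw = get("N")
    return AssociationRecord(
        snp_id=get("SNP"),
        chrom=str(get("CHR")),
        pos_bp=int(get("POS")),
        effect_allele=get("EA"),
        other_allele=get("OA"),
        eaf=float(eaf_raw) if eaf_raw is not None else None,
        beta=float(get("BETA")),
        se=float(get("SE")),
        pval=float(get("P")),
        n=int(float(n_raw)) if n_raw is not None else 0,
    )


def write_sumstats(records: Iterable[AssociationRecord], path: str | Path) -> None:
    """Write records in the standard tab-delimited dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(STANDARD_COLUMNS) + "\n")
        for r in records:
            eaf = "" if r.eaf is None else repr(r.eaf)
            fh.write(
                f"{r.snp_id}\t{r.chrom}\t{r.pos_bp}\t{r.effect_allele}\t{r.other_allele}"
                f"\t{eaf}\t{r.beta!r}\t{r.se!r}\t{r.pval!r}\t{r.n}\n"
            )


def read_r2_table(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a three-column (snp_a, snp_b, r2) table; symmetric completion applied."""
    table: dict[tuple[str, str], float] = {}
    with Path(path).open() as fh:
        first = fh.readline()
        rows = [] if not first.strip() else [first]
        rows += fh.readlines()
    for line in rows:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or parts[0].lower() in ("snp_a", "snp1"):
            continue
        a, b, r2 = parts[0], parts[1], float(parts[2])
        table[(a, b)] = r2
        table[(b, a)] = r2
    return table


def clump(
    records: Sequence[AssociationRecord],
    r2: Mapping[tuple[str, str], float] | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> list[AssociationRecord]:
    """Greedy p-value clumping.

    SNPs are visited in order of ascending p-value; a SNP is accepted iff
    no previously accepted SNP on the same chromosome is both within
    ``window_kb`` and in LD with it at r² >= ``r2_max``.  A missing r²
    entry for an in-window pair is an error naming the pair.  Output is
    sorted by (chrom, position).
    """
    r2 = r2 or {}
    window_bp = window_kb * 1000
    accepted: list[AssociationRecord] = []
    order = sorted(records, key=lambda r: (r.pval, r.snp_id))
    for rec in order:
        keep = True
        for acc in accepted:
            if acc.chrom != rec.chrom or abs(acc.pos_bp - rec.pos_bp) > window_bp:
                continue
            pair = (acc.snp_id, rec.snp_id)
            if pair not in r2:
                raise SumstatsError(
                    f"no r2 entry for in-window pair ({acc.snp_id}, {rec.snp_id})"
                )
            if r2[pair] >= r2_max:
                keep = False
                break
        if keep:
            accepted.append(rec)
    return sorted(accepted, key=lambda r: (r.chrom, r.pos_bp))


def _aligned_outcome(exp: AssociationRecord, out: AssociationRecord) -> AssociationRecord | None:
    """Align ``out`` onto ``exp``'s effect allele when the (unordered) allele
    pairs match directly; returns None when they do not."""
    if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
        return out
    if (out.effect_allele, out.other_allele) == (exp.other_allele, exp.effect_allele):
        return replace(
            out,
            effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
            beta=-out.beta,
            eaf=None if out.eaf is None else 1.0 - out.eaf,
        )
    return None


def harmonize(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    palindrome_maf_limit: float = 0.42,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedInstrumentSet:
    """Align exposure and outcome effects onto the exposure effect-allele frame.

    Per SNP present in both tables: matching allele pairs keep (or
    sign-flip) the outcome beta; palindromic pairs are oriented by allele
    frequency agreement and dropped as ambiguous when either trait's MAF
    exceeds ``palindrome_maf_limit``; anything else is dropped with an
    explicit reason.  Every input exposure SNP ends up either in
    ``snp_ids`` or in ``dropped``.
    """
    if not (0.0 < palindrome_maf_limit < 0.5):
        raise SumstatsError("palindrome_maf_limit must lie in (0, 0.5)")
    out_by_id = {r.snp_id: r for r in outcome}
    ids: list[str] = []
    gamma, sx, alpha, sy = [], [], [], []
    dropped: list[tuple[str, str]] = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            dropped.append((exp.snp_id, "missing in outcome"))
            continue
        if exp.is_palindromic:
            aligned = _aligned_outcome(exp, out)
            if aligned is None:
                dropped.append((exp.snp_id, "allele mismatch"))
                continue
            if exp.eaf is None or aligned.eaf is None:
                dropped.append((exp.snp_id, "palindrome without frequency"))
                continue
            if exp.maf > palindrome_maf_limit or aligned.maf > palindrome_maf_limit:
                dropped.append((exp.snp_id, "ambiguous palindrome"))
                continue
            # strand flip on a palindrome masquerades as matching alleles;
            # orient so the minor allele agrees between the two samples
            if (exp.eaf < 0.5) != (aligned.eaf < 0.5):
                aligned = replace(aligned, beta=-aligned.beta, eaf=1.0 - aligned.eaf)
        else:
            aligned = _aligned_outcome(exp, out)
            if aligned is None:
                out_pair = {out.effect_allele, out.other_allele}
                comp_pair = {COMPLEMENT[exp.effect_allele], COMPLEMENT[exp.other_allele]}
                reason = "strand mismatch" if out_pair == comp_pair else "allele mismatch"
                dropped.append((exp.snp_id, reason))
                continue
        ids.append(exp.snp_id)
        gamma.append(exp.beta)
        sx.append(exp.se)
        alpha.append(aligned.beta)
        sy.append(aligned.se)
    if not ids:
        raise SumstatsError("no usable instruments")
    return HarmonizedInstrumentSet(
        exposure_name, outcome_name, ids,
        np.array(gamma), np.array(sx), np.array(alpha), np.array(sy), dropped,
    )
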