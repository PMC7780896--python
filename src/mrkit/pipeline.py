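"""Study orchestration: per-pair method battery, selection, bidirectional
and replication analyses, and per-category Bonferroni reporting.

A study crosses a set of exposure summary-stat sources with a set of
outcome sources, each outcome tagged with a disease category.  For every
pair the pipeline selects instruments (genome-wide significance then
clumping), harmonizes, computes diagnostics, runs the five-method
battery (skipping any method whose preconditions fail, with the reason
recorded), applies the assumption-driven selector, and judges
significance of the recommended method against the category's Bonferroni
threshold alpha_family / (outcomes in category).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .diagnostics import DiagnosticsReport, diagnose
from .estimators import (
    DEFAULT_LAMBDA_GRID, Method, MRResult, egger, egger_simex, ivw, weighted_median,
)
from .presso import PressoReport, presso
from .selector import SelectorDecision, recommend
from .sumstats import (
    AssociationRecord, HarmonizedInstrumentSet, SumstatsError,
    clump, harmonize, read_r2_table, read_sumstats,
)

__all__ = [
    "OutcomeSpec", "StudyConfig", "PairReport", "StudyResult",
    "run_pair", "run_study", "bidirectional", "replicate",
    "derive_seed", "load_study_config",
]

ALL_METHODS = (Method.IVW, Method.EGGER, Method.EGGER_SIMEX,
               Method.WEIGHTED_MEDIAN, Method.PRESSO)


def derive_seed(*parts) -> int:
    """Deterministic sub-seed (< 2^31) from arbitrary hashable parts."""
    return zlib.crc32(repr(parts).encode()) & 0x7FFFFFFF


@dataclass
class OutcomeSpec:
    records: list[AssociationRecord]
    category: str
    replication: list[AssociationRecord] | None = None


@dataclass
class StudyConfig:
    exposures: dict[str, list[AssociationRecord]]
    outcomes: dict[str, OutcomeSpec]
    alpha_family: float = 0.05
    gwas_p_threshold: float = 5e-8
    r2: Mapping[tuple[str, str], float] | None = None
    r2_max: float = 0.001
    window_kb: float = 10_000
    palindrome_maf_limit: float = 0.42
    methods: tuple[Method, ...] = ALL_METHODS
    seed: int = 0
    simex_lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    simex_b_reps: int = 1000
    wm_n_boot: int = 1000
    presso_n_sim: int = 5000
    presso_outlier_alpha: float = 0.05

    def category_thresholds(self) -> dict[str, float]:
        counts: dict[str, int] = {}
        for spec in self.outcomes.values():
            counts[spec.category] = counts.get(spec.category, 0) + 1
        if not counts:
            raise ValueError("study has no outcome categories")
        return {cat: self.alpha_family / n for cat, n in counts.items()}


@dataclass
class PairReport:
    exposure: str
    outcome: str
    category: str
    estimable: bool
    reason: str | None = None
    hset: HarmonizedInstrumentSet | None = None
    diagnostics: DiagnosticsReport | None = None
    results: dict[Method, MRResult] = field(default_factory=dict)
    skipped: dict[Method, str] = field(default_factory=dict)
    presso_report: PressoReport | None = None
    decision: SelectorDecision | None = None
    bonferroni_threshold: float | None = None
    significant: bool = False
    warnings: list[str] = field(default_factory=list)
    reverse: "PairReport | None" = None
    replication: "PairReport | None" = None

    def primary_result(self) -> MRResult | None:
        """Result of the selector-recommended method (outlier-corrected
        PRESSO estimate when outliers were removed)."""
        if self.decision is None:
            return None
        m = self.decision.primary
        if m is Method.PRESSO and self.presso_report is not None:
            return self.presso_report.corrected_result or self.presso_report.raw_result
        return self.results.get(m)

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "category": self.category,
            "estimable": self.estimable,
            "reason": self.reason,
            "n_snps": None if self.hset is None else len(self.hset),
            "dropped": None if self.hset is None else self.hset.dropped,
            "diagnostics": None if self.diagnostics is None else json.loads(self.diagnostics.to_json()),
            "results": {m.value: r.to_dict() for m, r in self.results.items()},
            "skipped": {m.value: reason for m, reason in self.skipped.items()},
            "presso": None if self.presso_report is None else json.loads(self.presso_report.to_json()),
            "decision": None if self.decision is None else {
                "recommended": [m.value for m in self.decision.recommended],
                "rationale": self.decision.rationale,
            },
            "bonferroni_threshold": self.bonferroni_threshold,
            "significant": self.significant,
            "warnings": self.warnings,
            "reverse": None if self.reverse is None else self.reverse.to_dict(),
            "replication": None if self.replication is None else self.replication.to_dict(),
        }


@dataclass
class StudyResult:
    pairs: list[PairReport]
    summary: pd.DataFrame
    thresholds: dict[str, float]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        for pair in self.pairs:
            name = f"{pair.exposure}__{pair.outcome}".replace(" ", "_").replace("/", "-")
            (outdir / f"{name}.json").write_text(json.dumps(pair.to_dict(), indent=1))


def _select_instruments(
    records: Sequence[AssociationRecord], cfg: StudyConfig,
    restrict_to: set[str] | None = None,
) -> list[AssociationRecord]:
    if restrict_to is not None:
        # keep the clumped (chrom, pos) order so estimates reproduce exactly
        return sorted((r for r in records if r.snp_id in restrict_to),
                      key=lambda r: (r.chrom, r.pos_bp))
    sig = [r for r in records if r.pval < cfg.gwas_p_threshold]
    return clump(sig, cfg.r2, cfg.r2_max, cfg.window_kb)


def run_pair(
    exposure_records: Sequence[AssociationRecord],
    outcome_records: Sequence[AssociationRecord],
    cfg: StudyConfig,
    exposure_name: str,
    outcome_name: str,
    category: str = "",
    bonferroni_threshold: float | None = None,
    restrict_to: set[str] | None = None,
) -> PairReport:
    """Run the full battery for one exposure-outcome pair.

    Never raises for an under-powered pair: fewer than two harmonizable
    SNPs yields a report marked not estimable with the reasons attached.
    """
    report = PairReport(exposure_name, outcome_name, category, estimable=False,
                        bonferroni_threshold=bonferroni_threshold)
    instruments = _select_instruments(exposure_records, cfg, restrict_to)
    if not instruments:
        report.reason = "no genome-wide-significant instruments"
        return report
    try:
        hset = harmonize(instruments, outcome_records, cfg.palindrome_maf_limit,
                         exposure_name, outcome_name)
    except SumstatsError as exc:
        report.reason = str(exc)
        return report
    if len(hset) < 2:
        report.reason = "fewer than 2 harmonizable SNPs"
        report.hset = hset
        return report
    report.estimable = True
    report.hset = hset

    pair_seed = derive_seed(cfg.seed, exposure_name, outcome_name)

    presso_rep = None
    for method in cfg.methods:
        try:
            if method is Method.IVW:
                report.results[method] = ivw(hset)
            elif method is Method.EGGER:
                report.results[method] = egger(hset)
            elif method is Method.EGGER_SIMEX:
                report.results[method] = egger_simex(
                    hset, cfg.simex_lambda_grid, cfg.simex_b_reps,
                    seed=derive_seed(pair_seed, "simex"))
            elif method is Method.WEIGHTED_MEDIAN:
                report.results[method] = weighted_median(
                    hset, cfg.wm_n_boot, seed=derive_seed(pair_seed, "wm"))
            elif method is Method.PRESSO:
                presso_rep = presso(hset, cfg.presso_n_sim, cfg.presso_outlier_alpha,
                                    seed=derive_seed(pair_seed, "presso"))
                report.presso_report = presso_rep
                report.results[method] = (presso_rep.corrected_result
                                          or presso_rep.raw_result)
        except ValueError as exc:
            report.skipped[method] = str(exc)

    try:
        report.diagnostics = diagnose(
            hset, None if presso_rep is None else presso_rep.global_pval)
    except ValueError as exc:
        report.warnings.append(f"diagnostics unavailable: {exc}")
        return report
    try:
        report.decision = recommend(report.diagnostics)
    except ValueError as exc:
        report.warnings.append(f"selection unavailable: {exc}")
        return report

    primary = report.primary_result()
    if primary is not None and bonferroni_threshold is not None:
        report.significant = primary.slope_pval < bonferroni_threshold
    return report


def run_study(cfg: StudyConfig) -> StudyResult:
    """Full cross of exposures x outcomes; summary has one row per
    (exposure, outcome, method) attempted on an estimable pair."""
    thresholds = cfg.category_thresholds()
    pairs: list[PairReport] = []
    rows = []
    for exp_name, exp_records in cfg.exposures.items():
        for out_name, spec in cfg.outcomes.items():
            pair = run_pair(exp_records, spec.records, cfg, exp_name, out_name,
                            spec.category, thresholds[spec.category])
            if spec.replication is not None and pair.estimable:
                replicate(pair, cfg.exposures[exp_name], spec.replication, cfg)
            pairs.append(pair)
            if not pair.estimable:
                continue
            recommended = () if pair.decision is None else pair.decision.recommended
            for method in cfg.methods:
                res = pair.results.get(method)
                row = {
                    "exposure": exp_name,
                    "outcome": out_name,
                    "category": spec.category,
                    "method": method.value,
                    "status": "estimated" if res is not None else "skipped",
                    "slope": None if res is None else res.slope,
                    "se": None if res is None else res.slope_se,
                    "ci_low": None if res is None else res.slope_ci[0],
                    "ci_high": None if res is None else res.slope_ci[1],
                    "pval": None if res is None else res.slope_pval,
                    "n_snps": None if res is None else res.n_snps_used,
                    "recommended": method in recommended,
                    "bonferroni_threshold": thresholds[spec.category],
                    "significant": pair.significant and method in recommended[:1],
                    "skip_reason": pair.skipped.get(method),
                }
                rows.append(row)
    summary = pd.DataFrame(rows)
    return StudyResult(pairs=pairs, summary=summary, thresholds=thresholds)


def bidirectional(
    pair: PairReport,
    exposure_records: Sequence[AssociationRecord],
    outcome_records: Sequence[AssociationRecord],
    cfg: StudyConfig,
) -> PairReport:
    """Rerun the pair with exposure and outcome roles swapped.

    Instruments for the reverse direction are re-selected from the
    outcome trait's own genome-wide-significant associations; with none,
    the reverse report is marked not estimable.
    """
    reverse = run_pair(outcome_records, exposure_records, cfg,
                       pair.outcome, pair.exposure, pair.category,
                       pair.bonferroni_threshold)
    pair.reverse = reverse
    return pair


def replicate(
    pair: PairReport,
    exposure_records: Sequence[AssociationRecord],
    replication_outcome: Sequence[AssociationRecord],
    cfg: StudyConfig,
) -> PairReport:
    """Re-run the pair's instruments against a replication outcome source.

    Diagnostics and method selection are recomputed on the replication
    data (the recommended method may change).  Coverage below 50% of the
    original instruments is recorded as a warning.
    """
    if pair.hset is None:
        raise ValueError("cannot replicate a pair with no harmonized set")
    ids = set(pair.hset.snp_ids)
    rep = run_pair(exposure_records, replication_outcome, cfg,
                   pair.exposure, pair.outcome,
                   pair.category, pair.bonferroni_threshold,
                   restrict_to=ids)
    rep.outcome = pair.outcome + " (replication)"
    covered = set() if rep.hset is None else set(rep.hset.snp_ids)
    if ids and len(covered & ids) < 0.5 * len(ids):
        rep.warnings.append(
            f"replication covers only {len(covered & ids)}/{len(ids)} instruments")
    pair.replication = rep
    return pair


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a declarative study config (YAML) naming summary-stat files.

    Layout::

        seed: 1
        alpha_family: 0.05
        r2_table: ld.tsv          # optional
        exposures:
          FPG: fpg.tsv
        outcomes:
          CAD:
            path: cad.tsv
            category: vascular
            replication: cad_rep.tsv   # optional
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def load_records(p):
        records, _ = read_sumstats(base / p)
        return records

    exposures = {name: load_records(p) for name, p in raw["exposures"].items()}
    outcomes = {}
    for name, spec in raw["outcomes"].items():
        outcomes[name] = OutcomeSpec(
            records=load_records(spec["path"]),
            category=spec["category"],
            replication=load_records(spec["replication"]) if spec.get("replication") else None,
        )
    kwargs = {}
    for key in ("alpha_family", "gwas_p_threshold", "seed", "r2_max", "window_kb",
                "palindrome_maf_limit", "simex_b_reps", "wm_n_boot",
                "presso_n_sim", "presso_outlier_alpha"):
        if key in raw:
            kwargs[key] = raw[key]
    r2 = read_r2_table(base / raw["r2_table"]) if raw.get("r2_table") else None
    return StudyConfig(exposures=exposures, outcomes=outcomes, r2=r2, **kwargs)
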