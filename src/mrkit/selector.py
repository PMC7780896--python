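"""Assumption-driven choice of MR method.

The decision logic mirrors the standard routing used in applied
two-sample MR when a battery of methods has been run:

* No heterogeneity (Q, Q' and the PRESSO global test all nonsignificant):
  IVW with strong instruments; the weighted median when instruments are
  weak (robust to a minority of invalid ones); SIMEX-corrected Egger when
  instruments are both weak and measured with error (I²_GX < 0.90) —
  with strong instruments the dilution a low I²_GX signals only affects
  the Egger slope, so IVW is retained.
* Heterogeneity with NOME violated: the Egger slope is diluted, so the
  SIMEX correction is recommended regardless of which test fired.
* Heterogeneity with NOME satisfied: the pattern of (Q, Q', RSS)
  significance decides between MR-Egger (Q fired but the Egger fit
  resolves it), IVW (only Q' or only RSS fired), and MR-PRESSO (all
  three fired, i.e. outlier-driven directional pleiotropy).

Patterns not observed in practice (e.g. only the PRESSO global test
significant) carry a low-confidence annotation in the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diagnostics import DiagnosticsReport
from .estimators import Method

__all__ = ["SelectorDecision", "recommend", "recommend_from_stats"]


@dataclass
class SelectorDecision:
    recommended: tuple[Method, ...]
    rationale: list[str]
    inputs_echo: dict

    @property
    def primary(self) -> Method:
        return self.recommended[0]


# (q_sig, q_prime_sig, rss_sig) -> methods, for heterogeneous sets with
# NOME satisfied; split by instrument strength.
_HET_NOME_OK_STRONG = {
    (True, True, True): (Method.PRESSO,),
    (True, True, False): (Method.EGGER,),
    (True, False, False): (Method.EGGER,),
    (False, True, False): (Method.IVW,),
    (False, False, True): (Method.IVW,),
    (False, True, True): (Method.IVW,),
    (True, False, True): (Method.EGGER, Method.PRESSO),
}
_HET_NOME_OK_WEAK = {
    (True, True, True): (Method.PRESSO,),
    (True, True, False): (Method.EGGER,),
    (True, False, False): (Method.EGGER,),
    (False, True, False): (Method.IVW,),
    (False, False, True): (Method.PRESSO,),
    (False, True, True): (Method.PRESSO,),
    (True, False, True): (Method.EGGER, Method.PRESSO),
}
# heterogeneity patterns actually exemplified by applied analyses; the
# rest are annotated low-confidence
_WELL_SUPPORTED = {(True, True, True), (True, False, False), (False, False, False)}


def recommend(diag: DiagnosticsReport) -> SelectorDecision:
    """Map diagnostic flags to the recommended MR method(s)."""
    rss = diag.rss_sig
    if rss is None:
        if diag.q_sig or diag.q_prime_sig:
            raise ValueError("incomplete diagnostics: missing presso_global_pval")
        rss = False
        assumed_rss = True
    else:
        assumed_rss = False

    weak = diag.weak_instruments
    nome_bad = diag.nome_violated
    pattern = (diag.q_sig, diag.q_prime_sig, rss)
    het = any(pattern)
    rationale: list[str] = []
    if assumed_rss:
        rationale.append("PRESSO global p absent; Q and Q' nonsignificant, RSS assumed nonsignificant")
    rationale.append(
        f"heterogeneity {'present' if het else 'absent'} "
        f"(Q {'sig' if pattern[0] else 'ns'}, Q' {'sig' if pattern[1] else 'ns'}, "
        f"RSS {'sig' if pattern[2] else 'ns'})"
    )
    rationale.append(f"instruments {'weak (mean F <= 10)' if weak else 'strong (mean F > 10)'}")
    rationale.append(f"NOME {'violated (I2_GX < 0.90)' if nome_bad else 'satisfied (I2_GX >= 0.90)'}")

    if not het:
        if not weak:
            rec = (Method.IVW,)
            rationale.append("no heterogeneity, strong instruments -> IVW"
                             + ("; low I2_GX noted but IVW is not dilution-prone" if nome_bad else ""))
        elif nome_bad:
            rec = (Method.EGGER_SIMEX,)
            rationale.append("no heterogeneity, weak instruments with measurement error -> MR-Egger (SIMEX)")
        else:
            rec = (Method.WEIGHTED_MEDIAN,)
            rationale.append("no heterogeneity but weak instruments -> weighted median as robust alternative")
    elif nome_bad:
        rec = (Method.EGGER_SIMEX,)
        rationale.append("heterogeneity with NOME violated -> MR-Egger (SIMEX)")
    else:
        table = _HET_NOME_OK_WEAK if weak else _HET_NOME_OK_STRONG
        rec = table[pattern]
        rationale.append(
            "heterogeneity with NOME satisfied -> " + ", ".join(m.value for m in rec)
        )
        if pattern not in _WELL_SUPPORTED:
            rationale.append("low-confidence rule: heterogeneity pattern not exemplified in applied tables")

    return SelectorDecision(recommended=rec, rationale=rationale, inputs_echo={
        "weak_instruments": weak,
        "nome_violated": nome_bad,
        "q_sig": pattern[0],
        "q_prime_sig": pattern[1],
        "rss_sig": pattern[2],
    })


def recommend_from_stats(
    mean_f: float,
    i2_gx: float,
    q_pval: float,
    q_prime_pval: float,
    presso_global_pval: float | None = None,
    j_snps: int = 0,
) -> SelectorDecision:
    """Convenience wrapper taking the five raw statistics directly.

    ``i2_gx`` may be on the 0-1 or the percent scale.
    """
    i2 = i2_gx / 100.0 if i2_gx > 1.0 else i2_gx
    diag = DiagnosticsReport(
        j_snps=j_snps, mean_f=mean_f, i2_gx=i2,
        q_stat=float("nan"), q_pval=q_pval,
        q_prime_stat=float("nan"), q_prime_pval=q_prime_pval,
        presso_global_pval=presso_global_pval,
    )
    return recommend(diag)
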