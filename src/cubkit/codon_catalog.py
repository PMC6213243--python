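"""Preferred, optimal, and rare codon calling.

Preferred codons are simply those with RSCU > 1 in a pooled gene set; rare
codons those with RSCU < 0.1.  Optimal codons require an expression
contrast: genes are ranked by CAI, the upper and lower tails (default 5%)
are pooled into high- and low-expression count tables, and each sense codon
of a multi-codon family is tested with a 2x2 Pearson chi-squared test
(codon vs rest of family, high vs low set, no continuity correction).  A
codon is called optimal when its relative usage is higher in the
high-expression set and the test is significant, with two tiers:
``strong`` (p < 0.01) and ``moderate`` (p < 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .genetic_code import STANDARD_CODE, CodonCountTable, GeneticCode
from .indices import GeneIndexProfile, RscuTable, rscu


def preferred_codons(table: RscuTable) -> set[str]:
    """Codons with RSCU strictly greater than 1."""
    return {c for c, v in table.rscu.items() if v > 1}


def rare_codons(table: RscuTable) -> set[str]:
    """Codons with RSCU strictly below 0.1 (including unused codons of
    populated families, whose RSCU is exactly 0)."""
    return {c for c, v in table.rscu.items() if v < 0.1}


@dataclass(frozen=True)
class ExpressionExtremes:
    """High- and low-CAI gene tails with their pooled codon counts."""

    high_ids: tuple[str, ...]
    low_ids: tuple[str, ...]
    fraction: float
    high_counts: CodonCountTable
    low_counts: CodonCountTable
    tied: bool = False


def expression_extremes(
    profiles: Sequence[GeneIndexProfile],
    tables: Mapping[str, CodonCountTable],
    fraction: float = 0.05,
) -> ExpressionExtremes:
    """Select the upper and lower CAI tails and pool their codon counts.

    Each tail holds ``ceil(fraction * N)`` genes (minimum one); ties on CAI
    are broken by gene id so the selection is deterministic.  Requires the
    two tails to be disjoint.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    scored = [(p.cai, p.gene_id) for p in profiles if p.cai is not None]
    if len(scored) < 2:
        raise ValueError("need at least two genes with a defined CAI")
    k = max(1, math.ceil(fraction * len(scored)))
    if 2 * k > len(scored):
        raise ValueError("tails overlap: too few genes for this fraction")
    by_cai = sorted(scored, key=lambda t: (t[0], t[1]))
    low = tuple(gid for _, gid in by_cai[:k])
    high = tuple(gid for _, gid in sorted(by_cai[-k:], key=lambda t: (-t[0], t[1])))
    tied = len({c for c, _ in scored}) == 1
    if tied:
        warnings.warn("all CAI values identical; tail selection is id-ordered")
    return ExpressionExtremes(
        high_ids=high,
        low_ids=low,
        fraction=fraction,
        high_counts=CodonCountTable.pool([tables[g] for g in high]),
        low_counts=CodonCountTable.pool([tables[g] for g in low]),
        tied=tied,
    )


@dataclass(frozen=True)
class OptimalCodonCall:
    """Per-codon decision record of the high/low expression contrast."""

    codon: str
    aa: str
    rscu_high: float
    rscu_low: float
    chi2: float
    p: float
    tier: str  # "strong" (*), "moderate" (@), or "none"
    small_sample: bool = False

    @property
    def flag(self) -> str:
        return {"strong": "*", "moderate": "@"}.get(self.tier, "")


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction on [[a,b],[c,d]]."""
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / den
    return chi2, float(stats.chi2.sf(chi2, df=1))


def optimal_codons(
    extremes: ExpressionExtremes,
    code: GeneticCode = STANDARD_CODE,
    strong_alpha: float = 0.01,
    moderate_alpha: float = 0.05,
    require_preferred_high: bool = False,
) -> list[OptimalCodonCall]:
    """Chi-squared contrast of codon usage between the CAI tails.

    For each sense codon of a family of size >= 2 present in both pooled
    tables, tests the 2x2 table [codon, rest-of-family] x [high, low].  A
    call requires ``rscu_high > rscu_low`` (directionality) and p below a
    tier threshold.  Expected cell counts below 5 set ``small_sample``.
    With ``require_preferred_high`` the codon must also have RSCU > 1 in
    the high-expression set.
    """
    rscu_high = rscu(extremes.high_counts, code)
    rscu_low = rscu(extremes.low_counts, code)
    calls: list[OptimalCodonCall] = []
    for aa in code.amino_acids:
        family = code.families[aa]
        if len(family) < 2:
            continue
        fam_high = sum(extremes.high_counts[c] for c in family)
        fam_low = sum(extremes.low_counts[c] for c in family)
        if fam_high == 0 or fam_low == 0:
            continue  # family absent from one tail: no contrast possible
        for codon in family:
            a, b = extremes.high_counts[codon], fam_high - extremes.high_counts[codon]
            c, d = extremes.low_counts[codon], fam_low - extremes.low_counts[codon]
            chi2, p = _chi2_2x2(a, b, c, d)
            n = a + b + c + d
            expected_min = min(
                (a + b) * (a + c), (a + b) * (b + d), (c + d) * (a + c), (c + d) * (b + d)
            ) / n
            rh, rl = rscu_high[codon], rscu_low[codon]
            tier = "none"
            if rh > rl and not (require_preferred_high and rh <= 1):
                if p < strong_alpha:
                    tier = "strong"
                elif p < moderate_alpha:
                    tier = "moderate"
            calls.append(
                OptimalCodonCall(
                    codon=codon,
                    aa=aa,
                    rscu_high=rh,
                    rscu_low=rl,
                    chi2=chi2,
                    p=p,
                    tier=tier,
                    small_sample=expected_min < 5,
                )
            )
    return calls
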