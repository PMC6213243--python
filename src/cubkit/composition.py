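"""Nucleotide-composition statistics with codon-exclusion rules, and PR2 bias.

The positional GC contents follow the conventions common in chloroplast
codon-usage studies:

* ``P1``/``P2`` (GC at codon positions 1 and 2) exclude only the
  single-codon families Met (AUG) and Trp (UGG), whose usage carries no
  synonymous signal.
* ``P3`` (GC at position 3) additionally excludes the three stop codons
  (UAA, UAG, UGA) and the three isoleucine codons (AUU, AUC, AUA), whose
  third position does not follow the regular 2-/4-fold substitution pattern.
* ``GC_cds`` is the plain GC fraction over every base of every codon.
* ``P12`` is the arithmetic mean of ``P1`` and ``P2``.

The parity-rule-2 (PR2) biases ``G3/(G3+C3)`` and ``A3/(A3+U3)`` are computed
over the same third-position codon universe as ``P3``.  Under a pure
mutation–drift equilibrium with no strand asymmetry both biases sit at 0.5;
departures indicate strand-specific mutation or selection.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genetic_code import STANDARD_CODE, CodonCountTable, GeneticCode

#: codons excluded from P1/P2: single-codon families.
SINGLE_CODONS = ("AUG", "UGG")
#: codons additionally excluded from P3: stops and the 3-fold Ile family.
P3_EXTRA_EXCLUDED = ("UAA", "UAG", "UGA", "AUU", "AUC", "AUA")


@dataclass(frozen=True)
class PositionalGc:
    """Positional GC fractions for a codon count table.

    Any field may be ``None`` when its codon universe is empty (for example
    a table containing only AUG and UGG codons).
    """

    gc_cds: float | None
    p1: float | None
    p2: float | None
    p3: float | None
    p12: float | None
    a3: float | None
    u3: float | None
    g3: float | None
    c3: float | None


@dataclass(frozen=True)
class Pr2Point:
    """PR2-plot coordinates; ``None`` marks an undefined (0/0) bias."""

    gc_bias: float | None
    au_bias: float | None


def _gc_fraction_at(
    counts: CodonCountTable, position: int, excluded: frozenset[str]
) -> float | None:
    total = 0
    gc = 0
    for codon, n in counts.counts.items():
        if codon in excluded:
            continue
        total += n
        if codon[position] in "GC":
            gc += n
    return gc / total if total else None


def p3_base_totals(counts: CodonCountTable) -> dict[str, int]:
    """Third-position base counts (A3, U3, G3, C3) over the P3 universe."""
    excluded = set(SINGLE_CODONS) | set(P3_EXTRA_EXCLUDED)
    totals = {"A": 0, "U": 0, "G": 0, "C": 0}
    for codon, n in counts.counts.items():
        if codon in excluded:
            continue
        totals[codon[2]] += n
    return totals


def positional_gc(
    counts: CodonCountTable, exclude_all_positions: bool = False
) -> PositionalGc:
    """Compute GC_cds, P1, P2, P3, P12 and the third-position base fractions.

    Parameters
    ----------
    counts:
        Codon counts for one gene or a pooled set.
    exclude_all_positions:
        When True, the stop and Ile exclusion is applied to P1 and P2 as
        well as P3 (the default applies it to P3 only).
    """
    if counts.n_total == 0:
        raise ValueError("empty codon count table")
    p12_excl = frozenset(SINGLE_CODONS) | (
        frozenset(P3_EXTRA_EXCLUDED) if exclude_all_positions else frozenset()
    )
    p3_excl = frozenset(SINGLE_CODONS) | frozenset(P3_EXTRA_EXCLUDED)

    gc_all = 0
    n_all = 0
    for codon, n in counts.counts.items():
        n_all += 3 * n
        gc_all += n * sum(1 for b in codon if b in "GC")
    gc_cds = gc_all / n_all if n_all else None

    p1 = _gc_fraction_at(counts, 0, p12_excl)
    p2 = _gc_fraction_at(counts, 1, p12_excl)
    p3 = _gc_fraction_at(counts, 2, p3_excl)
    p12 = (p1 + p2) / 2 if p1 is not None and p2 is not None else None

    totals = p3_base_totals(counts)
    n3 = sum(totals.values())
    fr = {b: (totals[b] / n3 if n3 else None) for b in "AUGC"}
    return PositionalGc(
        gc_cds=gc_cds,
        p1=p1,
        p2=p2,
        p3=p3,
        p12=p12,
        a3=fr["A"],
        u3=fr["U"],
        g3=fr["G"],
        c3=fr["C"],
    )


def pr2_biases(counts: CodonCountTable) -> Pr2Point:
    """GC bias G3/(G3+C3) and AU bias A3/(A3+U3) at third codon positions.

    A zero denominator yields ``None`` for that coordinate rather than a
    spurious 0.
    """
    t = p3_base_totals(counts)
    gc_den = t["G"] + t["C"]
    au_den = t["A"] + t["U"]
    return Pr2Point(
        gc_bias=t["G"] / gc_den if gc_den else None,
        au_bias=t["A"] / au_den if au_den else None,
    )


def genome_gc(genome_sequence: str) -> float:
    """GC fraction of a whole genome sequence.

    Ambiguous bases are excluded from the denominator; both DNA and RNA
    alphabets are accepted.
    """
    if not genome_sequence:
        raise ValueError("empty genome sequence")
    seq = genome_sequence.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "ATU")
    if gc + at == 0:
        raise ValueError("no unambiguous base in genome sequence")
    return gc / (gc + at)
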