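"""Per-gene codon usage bias indices: RSCU, ENc, CAI, GC3s, Gravy, Aromo.

RSCU
    Relative synonymous codon usage: observed count of a codon divided by
    the count expected if its synonymous family were used evenly.  Within a
    family of size *k* the values sum to *k*; RSCU = 1 means no bias.
ENc
    Wright's effective number of codons.  Per-family homozygosity
    ``F = (n * sum(p^2) - 1) / (n - 1)`` is averaged within each degeneracy
    class and combined as ``ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``.  ENc runs
    from 20 (one codon per amino acid) to 61 (perfectly even usage, after
    capping).
CAI
    Codon adaptation index: the count-weighted geometric mean of relative
    adaptiveness values *w* derived from a highly expressed reference gene
    or gene set.
GC3s
    GC fraction at the third position of synonymous codons (stop, AUG and
    UGG excluded; isoleucine included, unlike the composition module's P3).
Gravy / Aromo
    Mean Kyte-Doolittle hydropathy and the fraction of aromatic residues
    (Phe, Tyr, Trp) of the encoded protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .genetic_code import STANDARD_CODE, CdsRecord, CodonCountTable, GeneticCode, translate

AROMATIC = frozenset("FYW")


@dataclass(frozen=True)
class RscuTable:
    """RSCU values per codon plus the set of families absent from the data."""

    rscu: Mapping[str, float]
    undefined_families: frozenset[str]

    def __getitem__(self, codon: str) -> float:
        return self.rscu[codon]

    def get(self, codon: str, default: float | None = None) -> float | None:
        return self.rscu.get(codon, default)


def rscu(counts: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> RscuTable:
    """Relative synonymous codon usage for every populated family.

    The stop family is included as a regular 3-codon family.  Families whose
    total count is zero are reported as undefined rather than assigned a
    value.
    """
    values: dict[str, float] = {}
    undefined: set[str] = set()
    for aa, family in code.families.items():
        total = sum(counts[c] for c in family)
        if total == 0:
            undefined.add(aa)
            continue
        expected = total / len(family)
        for c in family:
            values[c] = counts[c] / expected
    return RscuTable(values, frozenset(undefined))


def family_homozygosity(counts: CodonCountTable, family: tuple[str, ...]) -> float | None:
    """Wright's F-hat for one synonymous family; None when n < 2 or F <= 0."""
    ns = [counts[c] for c in family]
    n = sum(ns)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in ns)
    f_hat = (n * sum_p2 - 1) / (n - 1)
    if f_hat <= 0:
        return None
    return f_hat


def enc(counts: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> float | None:
    """Wright's effective number of codons, capped at 61.

    Degeneracy classes follow the standard code (nine 2-fold families, Ile
    as the unique 3-fold family, five 4-fold and three 6-fold families; Met
    and Trp contribute the constant 2).  Families with fewer than two
    counted codons, or with non-positive homozygosity, are skipped.  A
    missing 3-fold class average is imputed as the mean of the 2- and 4-fold
    averages; any other missing class makes ENc undefined (``None``).
    """
    class_aas = code.degeneracy_classes()
    f_bar: dict[int, float | None] = {}
    for size in (2, 3, 4, 6):
        fs = [
            f
            for aa in class_aas.get(size, ())
            if (f := family_homozygosity(counts, code.families[aa])) is not None
        ]
        f_bar[size] = sum(fs) / len(fs) if fs else None
    if f_bar[3] is None and f_bar[2] is not None and f_bar[4] is not None:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2
    if any(f_bar[s] is None for s in (2, 3, 4, 6)):
        return None
    n_fams = {2: 9, 3: 1, 4: 5, 6: 3}
    value = 2.0 + sum(n_fams[s] / f_bar[s] for s in (2, 3, 4, 6))
    return min(value, 61.0)


@dataclass(frozen=True)
class CaiReference:
    """Relative adaptiveness table w(codon) derived from a reference gene set.

    ``w`` is defined only for sense codons of multi-codon families whose
    amino acid occurs in the reference; Met, Trp and stop codons never
    receive a value.
    """

    w: Mapping[str, float]
    provenance: str = ""

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("codon\tw\n")
            for codon in sorted(self.w):
                fh.write(f"{codon}\t{self.w[codon]:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "CaiReference":
        w: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.lower().startswith("codon"):
                raise ValueError("expected a 'codon\\tw' header")
            for line in fh:
                codon, value = line.split("\t")
                w[codon.strip().upper().replace("T", "U")] = float(value)
        return cls(w, provenance or str(path))


def cai_reference(
    ref_counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    floor: float = 0.01,
    provenance: str = "",
) -> CaiReference:
    """Build relative adaptiveness w = RSCU / max family RSCU from a reference.

    Codons unobserved in the reference receive the configurable floor
    (default 0.01) so that a single missing codon does not zero out the
    geometric mean of every gene using it.
    """
    if ref_counts.n_total == 0:
        raise ValueError("empty reference gene set")
    table = rscu(ref_counts, code)
    w: dict[str, float] = {}
    for aa, family in code.families.items():
        if aa in ("*", "M", "W") or len(family) < 2:
            continue
        if aa in table.undefined_families:
            continue
        max_rscu = max(table[c] for c in family)
        for c in family:
            w[c] = table[c] / max_rscu if table[c] > 0 else floor
    if not w:
        raise ValueError("reference populates no multi-codon family")
    return CaiReference(w, provenance)


def cai(counts: CodonCountTable, ref: CaiReference) -> float | None:
    """Codon adaptation index of a gene against a reference.

    Count-weighted geometric mean of w over the gene's codons; codons
    without a defined w (Met, Trp, stops, families absent from the
    reference) are excluded.  Returns ``None`` when no codon is scorable.
    """
    log_sum = 0.0
    n = 0
    for codon, count in counts.counts.items():
        w = ref.w.get(codon)
        if w is None:
            continue
        log_sum += count * math.log(w)
        n += count
    if n == 0:
        return None
    return math.exp(log_sum / n)


def gc3s(counts: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> float | None:
    """GC fraction at third positions of synonymous codons.

    The universe is every sense codon belonging to a multi-codon family
    (stops, AUG and UGG excluded; Ile included).
    """
    total = 0
    gc = 0
    for codon, n in counts.counts.items():
        aa = code.codon_to_aa[codon]
        if aa == "*" or len(code.families[aa]) < 2:
            continue
        total += n
        if codon[2] in "GC":
            gc += n
    return gc / total if total else None


def gravy(protein: str) -> float:
    """Mean Kyte-Doolittle hydropathy over all residues."""
    if not protein:
        raise ValueError("empty protein")
    return sum(KYTE_DOOLITTLE[a] for a in protein) / len(protein)


def aromo(protein: str) -> float:
    """Fraction of aromatic residues (Phe, Tyr, Trp)."""
    if not protein:
        raise ValueError("empty protein")
    return sum(1 for a in protein if a in AROMATIC) / len(protein)


@dataclass
class GeneIndexProfile:
    """All scalar indices for one gene, one row of the per-gene report."""

    gene_id: str
    length_aa: int
    gc_cds: float | None
    p1: float | None
    p2: float | None
    p12: float | None
    p3: float | None
    gc3s: float | None
    cai: float | None
    enc: float | None
    gravy: float | None
    aromo: float | None
    category: str = "Unassigned"

    FIELDS = (
        "gene_id",
        "length_aa",
        "gc_cds",
        "p1",
        "p2",
        "p12",
        "p3",
        "gc3s",
        "cai",
        "enc",
        "gravy",
        "aromo",
        "category",
    )


def gene_index_profile(
    cds: CdsRecord,
    ref: CaiReference,
    code: GeneticCode = STANDARD_CODE,
) -> GeneIndexProfile:
    """Compute the full index row for one CDS."""
    from . import composition
    from .genetic_code import count_codons

    counts = count_codons(cds)
    pos = composition.positional_gc(counts)
    protein = translate(cds, code).protein
    return GeneIndexProfile(
        gene_id=cds.gene_id,
        length_aa=cds.length_aa,
        gc_cds=pos.gc_cds,
        p1=pos.p1,
        p2=pos.p2,
        p12=pos.p12,
        p3=pos.p3,
        gc3s=gc3s(counts, code),
        cai=cai(counts, ref),
        enc=enc(counts, code),
        gravy=gravy(protein) if protein else None,
        aromo=aromo(protein) if protein else None,
        category=cds.category,
    )
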