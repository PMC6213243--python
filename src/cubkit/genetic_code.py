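"""Standard genetic-code model, CDS validation, and codon counting.

Everything downstream (composition statistics, CUB indices, codon catalogs,
correspondence analysis) consumes the two containers defined here: a
:class:`CdsRecord` for one protein-coding sequence and a
:class:`CodonCountTable` holding its 64-codon count vector.

Codons are represented in the RNA alphabet throughout; DNA input is converted
on ingestion (T -> U).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio.Data import CodonTable

RNA_BASES = "ACGU"
_ALLOWED_CHARS = frozenset("ACGUBDHKMNRSVWY")  # IUPAC nucleotide letters, post T->U


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class EmptyGeneError(ValueError):
    """No countable codon survives validation."""


def _standard_code_mapping() -> dict[str, str]:
    table = CodonTable.unambiguous_rna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code over the RNA alphabet.

    Attributes
    ----------
    codon_to_aa:
        Map from each of the 64 codons to a one-letter amino acid, with
        ``"*"`` for the three stop codons.
    families:
        Partition of the 64 codons into 21 synonymous families (20 amino
        acids plus the stop family), keyed by the one-letter symbol.
    """

    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]]

    @classmethod
    def standard(cls) -> "GeneticCode":
        mapping = _standard_code_mapping()
        fams: dict[str, list[str]] = {}
        for codon in sorted(mapping):
            fams.setdefault(mapping[codon], []).append(codon)
        return cls(
            codon_to_aa=mapping,
            families={aa: tuple(cs) for aa, cs in fams.items()},
        )

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in self.codons if self.codon_to_aa[c] != "*")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return self.families["*"]

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(aa for aa in sorted(self.families) if aa != "*")

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Group amino acids (not stop) by synonymous-family size.

        Returns a map from family size (1, 2, 3, 4, 6 under the standard
        code) to the amino acids whose family has that size.
        """
        out: dict[int, list[str]] = {}
        for aa in self.amino_acids:
            out.setdefault(len(self.families[aa]), []).append(aa)
        return {k: tuple(v) for k, v in sorted(out.items())}


#: Module-level singleton used as the default by every operation.
STANDARD_CODE = GeneticCode.standard()


def normalize_sequence(raw_sequence: str) -> str:
    """Uppercase a nucleotide string and convert the DNA alphabet to RNA."""
    if not raw_sequence:
        raise EmptyGeneError("empty sequence")
    seq = raw_sequence.strip().upper().replace("T", "U")
    bad = set(seq) - _ALLOWED_CHARS
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")
    return seq


def normalize_and_validate(raw_sequence: str) -> tuple[list[str], int]:
    """Validate a CDS and return its in-frame codons.

    Returns ``(codons, n_excluded)`` where ``codons`` contains only clean
    A/C/G/U triplets and ``n_excluded`` counts codons dropped because they
    contained an ambiguous base (N or other IUPAC letters).  Ambiguity is a
    per-codon exclusion, not a gene-level failure, so that draft annotations
    with scattered Ns remain analysable.

    Raises
    ------
    FrameError
        If the length is not a multiple of three.
    EmptyGeneError
        If the input is empty or no codon survives filtering.
    """
    seq = normalize_sequence(raw_sequence)
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} is not a multiple of 3")
    codons = []
    n_excluded = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if all(b in RNA_BASES for b in codon):
            codons.append(codon)
        else:
            n_excluded += 1
    if not codons:
        raise EmptyGeneError("no unambiguous codon left after filtering")
    return codons, n_excluded


@dataclass
class CdsRecord:
    """One protein-coding sequence with identity and annotation metadata.

    ``category`` is the functional class used by the gene-set analyses
    (``Photo``, ``Genet``, ``Other`` or ``Unassigned``).
    """

    gene_id: str
    sequence: str
    species: str = ""
    product: str = ""
    category: str = "Unassigned"

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if len(self.sequence) % 3 != 0:
            raise FrameError(
                f"{self.gene_id}: length {len(self.sequence)} not a multiple of 3"
            )

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def length_aa(self) -> int:
        """Protein length in residues (terminal stop not counted)."""
        n = self.length_nt // 3
        last = self.sequence[-3:]
        if STANDARD_CODE.codon_to_aa.get(last) == "*":
            n -= 1
        return n

    def codons(self) -> list[str]:
        return normalize_and_validate(self.sequence)[0]


@dataclass(frozen=True)
class CodonCountTable:
    """A 64-codon count vector for one gene or a pooled gene set.

    Pooling is plain vector addition (``table_a + table_b``), which is
    associative and commutative; ``source_ids`` accumulates the contributing
    gene identifiers.
    """

    counts: Mapping[str, int]
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(STANDARD_CODE.codons)
        if unknown:
            raise ValueError(f"unknown codons: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon count")

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {
            c: self[c] + other[c]
            for c in STANDARD_CODE.codons
            if self[c] + other[c] > 0
        }
        return CodonCountTable(merged, self.source_ids + other.source_ids)

    def family_total(self, aa: str, code: GeneticCode = STANDARD_CODE) -> int:
        return sum(self[c] for c in code.families[aa])

    @classmethod
    def from_codons(
        cls, codons: Iterable[str], source_ids: tuple[str, ...] = ()
    ) -> "CodonCountTable":
        counts: dict[str, int] = {}
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
        return cls(counts, source_ids)

    @classmethod
    def pool(cls, tables: Sequence["CodonCountTable"]) -> "CodonCountTable":
        out = cls({})
        for t in tables:
            out = out + t
        return out


def count_codons(cds: CdsRecord | str) -> CodonCountTable:
    """Count all in-frame codons of a CDS, including the terminal stop.

    Codons containing ambiguous bases are excluded (see
    :func:`normalize_and_validate`); the table total is therefore
    ``length_nt/3`` minus the number of excluded codons.
    """
    if isinstance(cds, CdsRecord):
        codons, _ = normalize_and_validate(cds.sequence)
        ids: tuple[str, ...] = (cds.gene_id,)
    else:
        codons, _ = normalize_and_validate(cds)
        ids = ()
    return CodonCountTable.from_codons(codons, ids)


class Translation(NamedTuple):
    protein: str
    premature_stop: bool


def translate(cds: CdsRecord | str, code: GeneticCode = STANDARD_CODE) -> Translation:
    """Standard-code translation with the trailing stop dropped.

    An internal stop codon does not abort translation; it is skipped and
    reported through the ``premature_stop`` flag, since the analyses that
    consume proteins (hydropathy, aromaticity) average over residues.
    Ambiguous codons are skipped silently.
    """
    codons = cds.codons() if isinstance(cds, CdsRecord) else normalize_and_validate(cds)[0]
    aas = [code.codon_to_aa[c] for c in codons]
    if aas and aas[-1] == "*":
        aas = aas[:-1]
    premature = "*" in aas
    return Translation("".join(a for a in aas if a != "*"), premature)


def shuffle_codons(codons: Sequence[str], seed: int) -> list[str]:
    """Return a seeded random permutation of a codon list (test utility)."""
    rng = random.Random(seed)
    out = list(codons)
    rng.shuffle(out)
    return out
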