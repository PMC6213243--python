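"""Length filtering and functional classification of chloroplast CDS.

Chloroplast protein-coding genes split naturally into photosynthesis-related
genes (``Photo``: photosystems, electron transport chain, ATP synthase,
RuBisCO), genetic-system genes (``Genet``: ribosomal proteins, RNA
polymerase, maturase), and a residual ``Other`` group (hypothetical reading
frames, envelope membrane protein, Clp protease).  Classification is driven
by the free-text ``product`` annotation through an ordered, case-insensitive
substring rule list; the first matching rule wins and unmatched products
fall back to ``Unassigned``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genetic_code import CdsRecord

CATEGORIES = ("Photo", "Genet", "Other")

#: Default rule vocabulary for chloroplast product annotations.
DEFAULT_RULE_LIST: tuple[tuple[str, str], ...] = (
    ("nadh-plastoquinone oxidoreductase", "Photo"),
    ("nadh dehydrogenase", "Photo"),
    ("atp synthase", "Photo"),
    ("photosystem ii", "Photo"),
    ("photosystem i", "Photo"),
    ("cytochrome b6/f", "Photo"),
    ("cytochrome b6-f", "Photo"),
    ("ycf3", "Photo"),
    ("ycf4", "Photo"),
    ("ribulose-1,5-bisphosphate carboxylase", "Photo"),
    ("ribulose 1,5-bisphosphate carboxylase", "Photo"),
    ("rubisco", "Photo"),
    ("cytochrome c heme attachment", "Photo"),
    ("cytochrome c biogenesis", "Photo"),
    ("acetyl-coa carboxylase", "Photo"),
    ("ribosomal protein", "Genet"),
    ("rna polymerase", "Genet"),
    ("maturase", "Genet"),
    ("rf1", "Other"),
    ("rf2", "Other"),
    ("ycf1", "Other"),
    ("ycf2", "Other"),
    ("envelope membrane protein", "Other"),
    ("clp protease", "Other"),
)


@dataclass(frozen=True)
class CategoryRules:
    """Ordered (pattern, category) rules over product annotations."""

    rules: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for pattern, category in self.rules:
            if category not in CATEGORIES:
                raise ValueError(f"unknown category {category!r} for {pattern!r}")
            if not pattern:
                raise ValueError("empty pattern")

    @classmethod
    def default(cls) -> "CategoryRules":
        return cls(DEFAULT_RULE_LIST)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CategoryRules":
        rules = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                pattern, category = line.split("\t")
                rules.append((pattern.lower(), category))
        return cls(tuple(rules))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for pattern, category in self.rules:
                fh.write(f"{pattern}\t{category}\n")


def classify_gene(product: str, rules: CategoryRules | None = None) -> str:
    """Assign a functional category to a product annotation.

    Matching is case-insensitive substring search in rule order; no match
    yields ``Unassigned``.
    """
    rules = rules or CategoryRules.default()
    text = product.lower()
    for pattern, category in rules.rules:
        if pattern in text:
            return category
    return "Unassigned"


def classify_records(
    records: Iterable[CdsRecord], rules: CategoryRules | None = None
) -> list[CdsRecord]:
    """Set ``category`` on each record from its product annotation (in place)."""
    out = []
    for rec in records:
        rec.category = classify_gene(rec.product, rules)
        out.append(rec)
    return out


@dataclass(frozen=True)
class LengthFilterReport:
    retained: tuple[str, ...]
    excluded: tuple[tuple[str, int], ...]  # (gene_id, length_nt)


def filter_by_length(
    records: Sequence[CdsRecord], threshold_nt: int = 300
) -> tuple[list[CdsRecord], LengthFilterReport]:
    """Drop CDS strictly shorter than ``threshold_nt`` (default 300 nt).

    Short CDS give noisy codon statistics; the boundary is inclusive
    (a 300 nt CDS is retained).  Returns the retained records and a report
    listing the excluded ids with their lengths.
    """
    kept = [r for r in records if r.length_nt >= threshold_nt]
    dropped = [(r.gene_id, r.length_nt) for r in records if r.length_nt < threshold_nt]
    return kept, LengthFilterReport(
        retained=tuple(r.gene_id for r in kept), excluded=tuple(dropped)
    )
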