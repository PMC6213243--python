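"""Readers for GenBank flat files and FASTA+metadata gene sets, TSV writers.

GenBank locations are 1-based inclusive in the file; Biopython converts them
to 0-based half-open internally and handles ``complement`` and ``join``
operators, so spliced and reverse-strand CDS come out ready to translate.
CDS with partial locations or lengths that are not a multiple of three are
rejected into a log rather than aborting the genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .composition import genome_gc
from .genetic_code import CdsRecord, FrameError


@dataclass
class GenomeRecord:
    """A genome sequence with its extracted CDS complement."""

    accession: str
    species: str
    genome_sequence: str
    cds_records: list[CdsRecord]
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def gc_genome(self) -> float:
        return genome_gc(self.genome_sequence)


def _feature_id(feature, fallback: str) -> str:
    for key in ("gene", "locus_tag", "protein_id"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return fallback


def read_genbank(path: str | Path) -> GenomeRecord:
    """Extract the genome sequence and every CDS feature from a GenBank file.

    Strand and join/complement locations are honored.  Partial-location CDS
    and CDS whose length is not a multiple of three go to the rejection log.
    Duplicate annotations (e.g. genes repeated in the inverted repeats) are
    kept as separate records, suffixed to stay unique.
    """
    record = SeqIO.read(str(path), "genbank")
    species = record.annotations.get("organism", "")
    seen: dict[str, int] = {}
    cds_records: list[CdsRecord] = []
    rejected: list[tuple[str, str]] = []
    idx = 0
    for feature in record.features:
        if feature.type != "CDS":
            continue
        idx += 1
        base_id = _feature_id(feature, f"CDS_{idx}")
        seen[base_id] = seen.get(base_id, 0) + 1
        gene_id = base_id if seen[base_id] == 1 else f"{base_id}.{seen[base_id]}"
        loc = str(feature.location)
        if "<" in loc or ">" in loc:
            rejected.append((gene_id, "partial location"))
            continue
        seq = str(feature.extract(record.seq))
        product = feature.qualifiers.get("product", [""])[0]
        try:
            cds_records.append(
                CdsRecord(
                    gene_id=gene_id,
                    sequence=seq,
                    species=species,
                    product=product,
                )
            )
        except (FrameError, ValueError) as exc:
            rejected.append((gene_id, str(exc)))
    return GenomeRecord(
        accession=record.id,
        species=species,
        genome_sequence=str(record.seq),
        cds_records=cds_records,
        rejected=rejected,
    )


def read_fasta_with_metadata(
    fasta_path: str | Path, tsv_path: str | Path | None = None
) -> list[CdsRecord]:
    """Load a CDS FASTA and merge the optional metadata sidecar TSV.

    The TSV must have a ``gene_id`` column and may carry ``species``,
    ``product`` and ``category``.  FASTA ids absent from the TSV get a
    warning and remain ``Unassigned``; duplicate FASTA ids are an error.
    """
    seqs: dict[str, str] = {}
    with open(fasta_path, encoding="utf-8") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
    meta: dict[str, dict] = {}
    if tsv_path is not None:
        df = pd.read_csv(tsv_path, sep="\t", dtype=str, na_values=["."])
        if "gene_id" not in df.columns:
            raise ValueError("metadata TSV needs a 'gene_id' column")
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in metadata TSV")
        meta = df.set_index("gene_id").to_dict("index")
        unmatched = set(meta) - set(seqs)
        if unmatched:
            warnings.warn(f"metadata rows without sequence: {sorted(unmatched)[:5]}")
    records = []
    for gene_id, seq in seqs.items():
        row = meta.get(gene_id)
        if row is None and tsv_path is not None:
            warnings.warn(f"no metadata for {gene_id}; category left Unassigned")
        row = row or {}
        def _get(key: str, default: str = "") -> str:
            value = row.get(key)
            return default if value is None or pd.isna(value) else str(value)
        records.append(
            CdsRecord(
                gene_id=gene_id,
                sequence=seq,
                species=_get("species"),
                product=_get("product"),
                category=_get("category", "Unassigned"),
            )
        )
    return records


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report table: UTF-8, tab-delimited, '.' for missing values."""
    df.to_csv(path, sep="\t", index=False, na_rep=".", encoding="utf-8")
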