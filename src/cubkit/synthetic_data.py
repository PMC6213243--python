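"""Synthetic CDS datasets with controllable codon-usage structure.

The generator emulates the statistical regimes that shape organellar codon
usage so that every analysis stage can be exercised without downloading
genomes:

``mixed`` (default)
    Amino acids are drawn from a composition vector; within each synonymous
    family, codon probabilities are shaped by a third-position GC pressure,
    an expression-scaled selection multiplier on a designated preferred
    codon set, and a purine/pyrimidine third-position skew.
``mutation``
    Mutational pressure acts on all three codon positions: bases are drawn
    directly, with the per-gene GC probability at positions 1+2 linearly
    linked to the per-gene third-position GC probability
    (``q12 = a + b * q3 + noise``).  Neutrality-plot regression of P12 on
    P3 should recover the slope ``b``.
``selection``
    The third position is decoupled from the per-gene mutational parameter:
    its GC content tracks expression-linked selection
    (``q3 = gc3_pressure + amplitude * (expression - 1/2)``) while positions
    1+2 vary independently within the narrow range protein conservation
    allows, so the neutrality-plot slope is near zero.

Defaults mirror a single plastid genome's coding complement: 57 genes of
430 codons, with category labels drawn from the chloroplast product
vocabulary in proportions of roughly 31 photosynthesis, 21 genetic-system
and 5 other genes.  The seed fully determines the output; per-gene
substreams are derived from the dataset seed and the gene index, so
regenerating any prefix of the dataset reproduces it exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genetic_code import STANDARD_CODE, CdsRecord
from .gene_sets import classify_gene

PHOTO_PRODUCTS = (
    "photosystem II protein D1",
    "photosystem I P700 apoprotein A1",
    "ATP synthase CF1 alpha subunit",
    "NADH-plastoquinone oxidoreductase subunit 1",
    "cytochrome b6/f complex subunit IV",
    "ribulose-1,5-bisphosphate carboxylase/oxygenase large subunit",
    "photosystem I assembly protein Ycf3",
    "cytochrome c heme attachment protein",
    "acetyl-CoA carboxylase beta subunit",
)
GENET_PRODUCTS = (
    "ribosomal protein S4",
    "ribosomal protein L2",
    "RNA polymerase beta subunit",
    "maturase K",
)
OTHER_PRODUCTS = (
    "hypothetical chloroplast RF1",
    "chloroplast envelope membrane protein",
    "clp protease proteolytic subunit",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset; the seed determines everything."""

    n_genes: int = 57
    codons_per_gene: int = 430
    aa_weights: tuple[float, ...] | None = None  # over the 20 amino acids, sorted
    gc3_pressure: float = 0.5
    selection_strength: float = 0.0
    preferred_set: frozenset[str] = frozenset()
    expression: str = "uniform"  # "uniform" grid on [0,1] or "lognormal"
    purine3_skew: float = 1.0
    regime: str = "mixed"  # "mutation", "selection", or "mixed"
    seed: int = 0
    # mutation-regime linear link between positions 1+2 and position 3
    p12_intercept: float = 0.20
    p12_slope: float = 0.50
    p12_noise_sd: float = 0.02
    gc3_range: tuple[float, float] = (0.15, 0.85)
    # selection regime: positions 1+2 constrained to a narrow band, and the
    # third position driven by expression rather than the mutational draw
    gc12_range: tuple[float, float] = (0.38, 0.52)
    selection_gc3_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.codons_per_gene < 1:
            raise ValueError("n_genes and codons_per_gene must be positive")
        if not 0 <= self.gc3_pressure <= 1:
            raise ValueError("gc3_pressure must lie in [0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be non-negative")
        if self.selection_strength > 0 and not self.preferred_set:
            raise ValueError("selection_strength > 0 requires a preferred_set")
        if self.regime not in ("mutation", "selection", "mixed"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.expression not in ("uniform", "lognormal"):
            raise ValueError(f"unknown expression model {self.expression!r}")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["preferred_set"] = sorted(self.preferred_set)
        Path(path).write_text(json.dumps(d, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        d["preferred_set"] = frozenset(d.get("preferred_set", ()))
        for key in ("aa_weights", "gc3_range", "gc12_range"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def pr2_balanced_aa_weights() -> tuple[float, ...]:
    """Amino-acid weights making the unbiased regime PR2-neutral.

    With even within-family codon usage the third-base universe is not
    automatically symmetric: six two-fold families end in U/C but only
    three (Gln, Lys, Glu) end in A/G, so uniform amino-acid sampling puts
    the PR2 point near (0.42, 0.42).  Upweighting Gln, Lys and Glu by 17/9
    zeroes the aggregate A3-U3 and G3-C3 imbalances, so that departures
    from (0.5, 0.5) in simulated data reflect the requested skew or
    selection and nothing else.  This is the default composition.
    """
    return tuple(
        17.0 / 9.0 if aa in ("E", "K", "Q") else 1.0
        for aa in STANDARD_CODE.amino_acids
    )


def _gene_rng(config: SimulationConfig, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(gene_index,))
    )


def _codon_probs(
    aa: str,
    gc3_pressure: float,
    selection_multiplier: float,
    preferred: frozenset[str],
    purine3_skew: float,
) -> tuple[tuple[str, ...], np.ndarray]:
    family = STANDARD_CODE.families[aa]
    w = np.empty(len(family))
    for i, codon in enumerate(family):
        b3 = codon[2]
        w[i] = gc3_pressure if b3 in "GC" else 1.0 - gc3_pressure
        if b3 in "AG":
            w[i] *= purine3_skew
        if codon in preferred:
            w[i] *= selection_multiplier
    total = w.sum()
    if total == 0:  # extreme pressure leaves no admissible codon: use evens
        w[:] = 1.0
        total = w.sum()
    return family, w / total


def simulate_gene(
    config: SimulationConfig,
    expression_level: float,
    rng: np.random.Generator,
    gc3_pressure: float | None = None,
) -> list[str]:
    """Sample one gene's body codons under the family-based (mixed) model.

    Amino acids come from ``config.aa_weights`` (PR2-balanced by default,
    see :func:`pr2_balanced_aa_weights`); codon
    choice within each family follows the third-position GC pressure, the
    expression-scaled selection multiplier ``1 + s * e`` on preferred
    codons, and the purine skew.  Returns the codon list without start or
    stop; callers append those.
    """
    q3 = config.gc3_pressure if gc3_pressure is None else gc3_pressure
    sel = 1.0 + config.selection_strength * expression_level
    aas = STANDARD_CODE.amino_acids
    weights = np.asarray(
        config.aa_weights if config.aa_weights is not None else pr2_balanced_aa_weights(),
        dtype=float,
    )
    if len(weights) != len(aas):
        raise ValueError(f"aa_weights must have length {len(aas)}")
    aa_idx = rng.choice(len(aas), size=config.codons_per_gene, p=weights / weights.sum())
    codons = np.empty(config.codons_per_gene, dtype=object)
    for i, aa in enumerate(aas):
        positions = np.nonzero(aa_idx == i)[0]
        if len(positions) == 0:
            continue
        family, probs = _codon_probs(
            aa, q3, sel, config.preferred_set, config.purine3_skew
        )
        codons[positions] = rng.choice(np.array(family, dtype=object), size=len(positions), p=probs)
    return list(codons)


_STOPS = ("UAA", "UAG", "UGA")


def _basewise_codons(
    n: int, q12: float, q3: float, rng: np.random.Generator
) -> list[str]:
    """Sample codons base-by-base (GC prob q12 at positions 1-2, q3 at 3),
    rejecting stop codons."""
    out: list[str] = []
    need = n
    while need > 0:
        m = int(need * 1.2) + 8  # oversample to cover stop rejections
        gc12 = rng.random((m, 2)) < q12
        gc3 = rng.random(m) < q3
        pick = rng.integers(0, 2, size=(m, 3))
        gu = np.array(["G", "C"])
        au = np.array(["A", "U"])
        b1 = np.where(gc12[:, 0], gu[pick[:, 0]], au[pick[:, 0]])
        b2 = np.where(gc12[:, 1], gu[pick[:, 1]], au[pick[:, 1]])
        b3 = np.where(gc3, gu[pick[:, 2]], au[pick[:, 2]])
        for c in ("".join(t) for t in zip(b1, b2, b3)):
            if c in _STOPS:
                continue
            out.append(c)
            need -= 1
            if need == 0:
                break
    return out


def _expression_levels(config: SimulationConfig) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2**20,))
    )
    if config.expression == "uniform":
        if config.n_genes == 1:
            return np.array([0.5])
        levels = np.linspace(0.0, 1.0, config.n_genes)
        rng.shuffle(levels)
        return levels
    x = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    return x / x.max()


def _products_for(config: SimulationConfig, n: int) -> list[str]:
    """Category-bearing product strings in plastid-like proportions."""
    if config.regime == "mutation":
        pool = GENET_PRODUCTS
        return [pool[i % len(pool)] for i in range(n)]
    if config.regime == "selection":
        pool = PHOTO_PRODUCTS
        return [pool[i % len(pool)] for i in range(n)]
    n_photo = round(n * 31 / 57)
    n_genet = round(n * 21 / 57)
    out = []
    for i in range(n):
        if i < n_photo:
            out.append(PHOTO_PRODUCTS[i % len(PHOTO_PRODUCTS)])
        elif i < n_photo + n_genet:
            out.append(GENET_PRODUCTS[i % len(GENET_PRODUCTS)])
        else:
            out.append(OTHER_PRODUCTS[i % len(OTHER_PRODUCTS)])
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Generate a full synthetic gene set plus its metadata table.

    Returns ``(records, metadata)`` where the metadata frame has columns
    ``gene_id, species, product, category, expression`` (and, for the
    base-sampled regimes, the per-gene generating parameters ``q12, q3``).
    """
    levels = _expression_levels(config)
    products = _products_for(config, config.n_genes)
    records: list[CdsRecord] = []
    meta_rows = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        rng = _gene_rng(config, i)
        q12 = q3 = np.nan
        if config.regime == "mutation":
            q3 = rng.uniform(*config.gc3_range)
            q12 = config.p12_intercept + config.p12_slope * q3 + rng.normal(
                0.0, config.p12_noise_sd
            )
            q12 = float(np.clip(q12, 0.02, 0.98))
            body = _basewise_codons(config.codons_per_gene, q12, q3, rng)
        elif config.regime == "selection":
            q12 = rng.uniform(*config.gc12_range)
            q3 = float(
                np.clip(
                    config.gc3_pressure
                    + config.selection_gc3_amplitude * (levels[i] - 0.5),
                    0.05,
                    0.95,
                )
            )
            body = _basewise_codons(config.codons_per_gene, q12, q3, rng)
        else:
            body = simulate_gene(config, levels[i], rng)
        stop = _STOPS[rng.integers(0, len(_STOPS))]
        gene_id = f"syn{i:0{width}d}"
        product = products[i]
        records.append(
            CdsRecord(
                gene_id=gene_id,
                sequence="AUG" + "".join(body) + stop,
                species="synthetic",
                product=product,
                category=classify_gene(product),
            )
        )
        meta_rows.append(
            (gene_id, "synthetic", product, records[-1].category, levels[i], q12, q3)
        )
    meta = pd.DataFrame(
        meta_rows,
        columns=["gene_id", "species", "product", "category", "expression", "q12", "q3"],
    )
    return records, meta


def write_fasta(records: Sequence[CdsRecord], path: str | Path) -> None:
    """Write records as DNA FASTA (U back-converted to T for file exchange)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            seq = rec.sequence.replace("U", "T")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, na_rep=".")
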