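"""Correspondence analysis of the gene x informative-codon RSCU matrix.

Classical (chi-square metric) correspondence analysis: the matrix of
per-gene RSCU values over the 59 informative codons (61 sense codons minus
the single-codon families AUG and UGG) is converted to a correspondence
matrix, centred by the outer product of row and column masses, standardised
by the chi-square metric, and factored by singular value decomposition.
Row (gene) and column (codon) principal coordinates share axes ordered by
explained inertia.  With 59 codons spread over 18 multi-codon families the
usage pattern has 59 - 18 = 41 degrees of freedom.

SVD axis signs are arbitrary, so a deterministic orientation is applied:
each axis is flipped, if necessary, so that its rank correlation with a
caller-supplied per-gene covariate (conventionally GC3s) is non-negative;
without a covariate, the first nonzero column score is made positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import STANDARD_CODE, CodonCountTable, GeneticCode
from .indices import GeneIndexProfile, rscu


def informative_codons(code: GeneticCode = STANDARD_CODE) -> tuple[str, ...]:
    """The 59 sense codons that carry synonymous information (no AUG/UGG)."""
    return tuple(
        c for c in code.sense_codons if len(code.family_of(c)) >= 2
    )


def degrees_of_freedom(code: GeneticCode = STANDARD_CODE) -> int:
    """Independent dimensions of synonymous usage: codons minus families."""
    multi = {aa for aa in code.amino_acids if len(code.families[aa]) >= 2}
    return len(informative_codons(code)) - len(multi)


def build_rscu_matrix(
    genes: Sequence[CodonCountTable],
    code: GeneticCode = STANDARD_CODE,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene x 59 matrix of RSCU values.

    Codons of families absent from a gene get 0 (no usage information).
    Row labels come from ``ids`` or, failing that, each table's first
    source id.
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    cols = informative_codons(code)
    if ids is None:
        ids = [
            (t.source_ids[0] if t.source_ids else f"gene{i}")
            for i, t in enumerate(genes)
        ]
    rows = []
    for table in genes:
        r = rscu(table, code)
        rows.append([r.get(c, 0.0) or 0.0 for c in cols])
    return pd.DataFrame(rows, index=list(ids), columns=list(cols))


@dataclass
class CoaResult:
    """Row/column principal coordinates and inertia decomposition."""

    row_scores: pd.DataFrame  # genes x retained axes
    col_scores: pd.DataFrame  # codons x retained axes
    inertia_fraction: np.ndarray  # all positive-inertia axes; sums to 1
    total_inertia: float
    n_codons: int
    dof: int

    @property
    def n_axes(self) -> int:
        return self.row_scores.shape[1]


def _orient(
    row: np.ndarray, col: np.ndarray, orient_by: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    flip = False
    if orient_by is not None and np.ptp(row) > 0 and np.ptp(orient_by) > 0:
        r = stats.spearmanr(row, orient_by).statistic
        if np.isfinite(r) and r != 0:
            flip = r < 0
        else:
            nz = col[np.nonzero(col)[0]]
            flip = len(nz) > 0 and nz[0] < 0
    else:
        nz = col[np.nonzero(col)[0]]
        flip = len(nz) > 0 and nz[0] < 0
    return (-row, -col) if flip else (row, col)


def correspondence_analysis(
    matrix: pd.DataFrame,
    n_axes: int = 4,
    orient_by: Sequence[float] | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> CoaResult:
    """Classical CA of a non-negative gene x codon matrix.

    Retains ``min(n_axes, rank)`` axes in the score tables; the inertia
    spectrum covers every axis with positive inertia and sums to one.  A
    matrix whose rows are all proportional has zero inertia and yields
    empty score tables.
    """
    X = np.asarray(matrix, dtype=float)
    if X.min() < 0:
        raise ValueError("matrix must be non-negative")
    grand = X.sum()
    if grand <= 0:
        raise ValueError("matrix grand total must be positive")
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any():
        raise ValueError("zero-mass row (gene with no counted codon)")
    keep = c > 0  # unused codons carry no inertia; scored as 0
    S = (P[:, keep] - np.outer(r, c[keep])) / np.sqrt(np.outer(r, c[keep]))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    tol = max(S.shape) * np.finfo(float).eps * (sv[0] if len(sv) else 0.0)
    sv = sv[sv > max(tol, 1e-12)]
    total_inertia = float((sv**2).sum())
    if total_inertia == 0 or len(sv) == 0:
        return CoaResult(
            row_scores=pd.DataFrame(index=matrix.index),
            col_scores=pd.DataFrame(index=matrix.columns),
            inertia_fraction=np.array([]),
            total_inertia=0.0,
            n_codons=matrix.shape[1],
            dof=degrees_of_freedom(code),
        )
    k = min(n_axes, len(sv))
    inertia_fraction = sv**2 / total_inertia
    ov = np.asarray(orient_by, dtype=float) if orient_by is not None else None
    rows = np.empty((X.shape[0], k))
    cols = np.empty((X.shape[1], k))
    for a in range(k):
        row = U[:, a] * sv[a] / np.sqrt(r)
        col_kept = Vt[a, :] * sv[a] / np.sqrt(c[keep])
        col = np.zeros(X.shape[1])
        col[keep] = col_kept
        rows[:, a], cols[:, a] = _orient(row, col, ov)
    axes = [f"Axis{a + 1}" for a in range(k)]
    return CoaResult(
        row_scores=pd.DataFrame(rows, index=matrix.index, columns=axes),
        col_scores=pd.DataFrame(cols, index=matrix.columns, columns=axes),
        inertia_fraction=inertia_fraction,
        total_inertia=total_inertia,
        n_codons=matrix.shape[1],
        dof=degrees_of_freedom(code),
    )


AXIS_INDEX_VARIABLES = ("gc_cds", "gc3s", "length_aa", "enc", "cai", "gravy", "aromo")


def axis_correlations(
    result: CoaResult,
    profiles: Sequence[GeneIndexProfile],
    variables: Sequence[str] = AXIS_INDEX_VARIABLES,
) -> pd.DataFrame:
    """Spearman correlation of each retained CA axis with each index.

    Returns a long-format frame with columns axis, index, r, p, tier where
    tier is ``*`` (p < 0.01), ``@`` (p < 0.05) or empty.  Gene sets must
    align between the CA result and the profiles.
    """
    by_id = {p.gene_id: p for p in profiles}
    missing = [g for g in result.row_scores.index if g not in by_id]
    if missing:
        raise ValueError(f"profiles missing for genes: {missing[:5]}")
    rows = []
    for axis in result.row_scores.columns:
        scores = result.row_scores[axis].to_numpy()
        for var in variables:
            vals = np.array(
                [
                    np.nan
                    if getattr(by_id[g], var) is None
                    else float(getattr(by_id[g], var))
                    for g in result.row_scores.index
                ]
            )
            mask = np.isfinite(vals)
            if mask.sum() < 3 or np.ptp(vals[mask]) == 0:
                rows.append((axis, var, np.nan, np.nan, ""))
                continue
            res = stats.spearmanr(scores[mask], vals[mask])
            tier = "*" if res.pvalue < 0.01 else ("@" if res.pvalue < 0.05 else "")
            rows.append((axis, var, float(res.statistic), float(res.pvalue), tier))
    return pd.DataFrame(rows, columns=["axis", "index", "r", "p", "tier"])
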