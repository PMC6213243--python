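"""Neutrality-plot regression, the ENc-GC3s expected curve, and Spearman
correlation matrices over gene index profiles.

The neutrality plot regresses P12 (mean GC at codon positions 1 and 2) on
P3 (GC at position 3) across genes.  Under pure mutational pressure all
three positions drift together and the slope approaches 1; under selective
constraint on the protein the slope flattens toward 0.  "Relative
neutrality" is the OLS slope expressed as a percentage.

The ENc-GC3s analysis compares each gene's observed ENc with the value
expected if composition alone drove codon usage,
``ENc = 2 + GC3s + 29 / (GC3s^2 + (1 - GC3s)^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indices import GeneIndexProfile


@dataclass(frozen=True)
class NeutralityFit:
    """OLS and Spearman summary of the P12-vs-P3 neutrality plot."""

    slope: float | None
    intercept: float | None
    spearman_r: float | None
    p_value: float | None
    n_genes: int

    @property
    def relative_neutrality_pct(self) -> float | None:
        return None if self.slope is None else 100.0 * self.slope


def neutrality_fit(profiles: Sequence[GeneIndexProfile]) -> NeutralityFit:
    """Fit the neutrality plot over genes with defined P12 and P3.

    Requires at least three usable genes.  A degenerate P3 (zero variance)
    yields an undefined slope rather than an arbitrary one.
    """
    pairs = [(p.p3, p.p12) for p in profiles if p.p3 is not None and p.p12 is not None]
    if len(pairs) < 3:
        raise ValueError("need at least three genes with defined P12 and P3")
    x = np.array([a for a, _ in pairs])
    y = np.array([b for _, b in pairs])
    if np.ptp(x) == 0:
        return NeutralityFit(None, None, None, None, len(pairs))
    ols = stats.linregress(x, y)
    sp = stats.spearmanr(x, y)
    return NeutralityFit(
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        spearman_r=float(sp.statistic),
        p_value=float(sp.pvalue),
        n_genes=len(pairs),
    )


def enc_expected(gc3s: float) -> float:
    """Composition-only expected ENc at a given GC3s.

    The closed form is meaningful on (0, 1); the endpoints are evaluated
    anyway with a warning since the expression stays finite there.
    """
    if not 0 <= gc3s <= 1:
        raise ValueError("gc3s must lie in [0, 1]")
    if gc3s in (0.0, 1.0):
        warnings.warn("ENc expectation at GC3s of exactly 0 or 1 is not meaningful")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


def enc_plot_points(profiles: Sequence[GeneIndexProfile]) -> pd.DataFrame:
    """Per-gene ENc-plot rows: observed ENc, expected ENc, relative deviation.

    ``deviation = (expected - observed) / expected``; genes missing ENc or
    GC3s appear with NaN entries.
    """
    rows = []
    for p in profiles:
        if p.gc3s is None or p.enc is None:
            rows.append((p.gene_id, p.gc3s, p.enc, np.nan, np.nan))
            continue
        exp = enc_expected(p.gc3s) if 0 < p.gc3s < 1 else np.nan
        dev = (exp - p.enc) / exp if np.isfinite(exp) else np.nan
        rows.append((p.gene_id, p.gc3s, p.enc, exp, dev))
    return pd.DataFrame(
        rows, columns=["gene_id", "gc3s", "enc_observed", "enc_expected", "deviation"]
    )


DEFAULT_VARIABLES = ("gc_cds", "p1", "p2", "p12", "p3", "gc3s", "cai", "enc", "gravy", "aromo")


def spearman_matrix(
    profiles: Sequence[GeneIndexProfile],
    variables: Sequence[str] = DEFAULT_VARIABLES,
    method: str = "spearman",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise rank correlations among index variables across genes.

    Returns ``(r, p)`` DataFrames indexed by variable.  Pairs are evaluated
    on genes where both variables are defined; constant variables give NaN
    entries.  ``method`` may be ``"spearman"`` (default) or ``"pearson"``.
    """
    if len(profiles) < 3:
        raise ValueError("need at least three genes")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    data = {
        v: np.array(
            [np.nan if getattr(p, v) is None else float(getattr(p, v)) for p in profiles]
        )
        for v in variables
    }
    k = len(variables)
    r = np.full((k, k), np.nan)
    pv = np.full((k, k), np.nan)
    for i, vi in enumerate(variables):
        for j, vj in enumerate(variables):
            if j < i:
                r[i, j], pv[i, j] = r[j, i], pv[j, i]
                continue
            mask = np.isfinite(data[vi]) & np.isfinite(data[vj])
            if mask.sum() < 3 or np.ptp(data[vi][mask]) == 0 or np.ptp(data[vj][mask]) == 0:
                continue
            if i == j:
                r[i, j], pv[i, j] = 1.0, 0.0
                continue
            res = corr(data[vi][mask], data[vj][mask])
            r[i, j], pv[i, j] = float(res.statistic), float(res.pvalue)
    idx = list(variables)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(pv, index=idx, columns=idx),
    )
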