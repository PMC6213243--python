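"""Simple SVG/PNG emitters for the three diagnostic plots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .indices import GeneIndexProfile
from .trend_analysis import NeutralityFit, enc_expected


def enc_plot(profiles: Sequence[GeneIndexProfile], path: str | Path) -> None:
    """Observed ENc against GC3s with the composition-only expectation curve."""
    xs = [p.gc3s for p in profiles if p.gc3s is not None and p.enc is not None]
    ys = [p.enc for p in profiles if p.gc3s is not None and p.enc is not None]
    grid = np.linspace(0.01, 0.99, 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(grid, [enc_expected(g) for g in grid], "k-", lw=1, label="expected")
    ax.scatter(xs, ys, s=12, alpha=0.7)
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENc")
    ax.set_ylim(15, 65)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pr2_plot(pr2_table: pd.DataFrame, path: str | Path) -> None:
    """AU bias vs GC bias per gene with the (0.5, 0.5) equilibrium cross."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pr2_table["gc_bias"], pr2_table["au_bias"], s=12, alpha=0.7)
    ax.axhline(0.5, color="k", lw=0.8)
    ax.axvline(0.5, color="k", lw=0.8)
    ax.set_xlabel("G3/(G3+C3)")
    ax.set_ylabel("A3/(A3+U3)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def neutrality_plot(
    profiles: Sequence[GeneIndexProfile], fit: NeutralityFit, path: str | Path
) -> None:
    """P12 against P3 per gene with the fitted regression line."""
    xs = [p.p3 for p in profiles if p.p3 is not None and p.p12 is not None]
    ys = [p.p12 for p in profiles if p.p3 is not None and p.p12 is not None]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(xs, ys, s=12, alpha=0.7)
    if fit.slope is not None and xs:
        grid = np.linspace(min(xs), max(xs), 50)
        ax.plot(grid, fit.intercept + fit.slope * grid, "r-", lw=1)
        ax.set_title(
            f"slope={fit.slope:.3f} ({100 * fit.slope:.1f}%), "
            f"r={fit.spearman_r:.3f}, p={fit.p_value:.3g}"
        )
    ax.set_xlabel("P3")
    ax.set_ylabel("P12")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
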