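"""End-to-end driver: from a gene set to the full report bundle.

Stages: length filter -> functional classification -> per-gene codon counts
and index profiles (CAI against a reference gene, by default any gene whose
id or product marks it as psbA, else the pooled gene set) -> pooled RSCU and
preferred/optimal/rare codon catalogs -> PR2, neutrality and ENc-plot data
-> correspondence analysis with axis-index correlations.  Every output is a
TSV (or the JSON run manifest) written to the chosen directory.
"""

from __future__ import annotations

import json
import math
import platform
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coa import axis_correlations, build_rscu_matrix, correspondence_analysis
from .codon_catalog import (
    expression_extremes,
    optimal_codons,
    preferred_codons,
    rare_codons,
)
from .composition import positional_gc, pr2_biases
from .gene_sets import CategoryRules, classify_records, filter_by_length
from .genetic_code import STANDARD_CODE, CdsRecord, CodonCountTable, count_codons
from .indices import CaiReference, GeneIndexProfile, cai_reference, gene_index_profile, rscu
from .io import write_tsv
from .trend_analysis import enc_plot_points, neutrality_fit, spearman_matrix


@dataclass(frozen=True)
class PipelineConfig:
    length_threshold_nt: int = 300
    cai_reference: str = "psbA"  # gene id/product keyword, or path to a w TSV
    tail_fraction: float = 0.05
    n_axes: int = 4
    exclude_all_positions: bool = False
    classify: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    profiles: list[GeneIndexProfile]
    profile_table: pd.DataFrame
    rscu_pooled: pd.DataFrame
    catalog: pd.DataFrame | None
    pr2_table: pd.DataFrame
    neutrality: dict
    enc_plot: pd.DataFrame
    coa_rows: pd.DataFrame | None
    coa_inertia: pd.DataFrame | None
    axis_corr: pd.DataFrame | None
    manifest: dict


def _resolve_reference(
    records: Sequence[CdsRecord], tables: dict[str, CodonCountTable], spec: str
) -> CaiReference:
    path = Path(spec)
    if path.suffix == ".tsv" and path.exists():
        return CaiReference.from_tsv(path)
    key = spec.lower()
    hits = [
        r.gene_id
        for r in records
        if key in r.gene_id.lower() or key in r.product.lower()
    ]
    if hits:
        pooled = CodonCountTable.pool([tables[g] for g in hits])
        return cai_reference(pooled, provenance=",".join(hits))
    warnings.warn(
        f"no gene matches CAI reference {spec!r}; using the pooled gene set"
    )
    pooled = CodonCountTable.pool(list(tables.values()))
    return cai_reference(pooled, provenance="pooled gene set")


def _profiles_frame(profiles: Sequence[GeneIndexProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(p, f) for f in GeneIndexProfile.FIELDS] for p in profiles],
        columns=list(GeneIndexProfile.FIELDS),
    )


def run_pipeline(
    records: Sequence[CdsRecord],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    rules: CategoryRules | None = None,
) -> PipelineResult:
    """Run the full analysis over one gene set.

    With ``outdir`` set, writes profiles.tsv, rscu.tsv, catalog.tsv,
    pr2.tsv, neutrality.tsv, encplot.tsv, spearman_r.tsv, coa_rows.tsv,
    coa_cols.tsv, coa_inertia.tsv, axis_correlations.tsv and manifest.json.
    Stages that need more structure than the input offers (codon catalog
    and CA need at least two genes) are skipped with a diagnostic.
    """
    config = config or PipelineConfig()
    if not records:
        raise ValueError("no input records")
    kept, report = filter_by_length(list(records), config.length_threshold_nt)
    if not kept:
        raise ValueError("no CDS survives the length filter")
    if config.classify:
        kept = classify_records(kept, rules)
    tables = {r.gene_id: count_codons(r) for r in kept}
    ref = _resolve_reference(kept, tables, config.cai_reference)
    profiles = [gene_index_profile(r, ref) for r in kept]
    prof_df = _profiles_frame(profiles)

    pooled = CodonCountTable.pool(list(tables.values()))
    pooled_rscu = rscu(pooled)
    pref = preferred_codons(pooled_rscu)
    rare = rare_codons(pooled_rscu)
    rscu_df = pd.DataFrame(
        [
            (
                STANDARD_CODE.codon_to_aa[c],
                c,
                pooled_rscu.rscu[c],
                "preferred" if c in pref else ("rare" if c in rare else ""),
            )
            for c in sorted(pooled_rscu.rscu)
        ],
        columns=["aa", "codon", "rscu", "class"],
    )

    catalog_df = None
    diagnostics: list[str] = []
    n_cai = sum(p.cai is not None for p in profiles)
    if n_cai >= 2 and math.ceil(config.tail_fraction * n_cai) * 2 <= n_cai:
        extremes = expression_extremes(profiles, tables, config.tail_fraction)
        calls = optimal_codons(extremes)
        catalog_df = pd.DataFrame(
            [
                (
                    c.aa,
                    c.codon,
                    c.rscu_high,
                    c.rscu_low,
                    c.chi2,
                    c.p,
                    c.tier,
                    c.flag,
                    c.small_sample,
                )
                for c in calls
            ],
            columns=[
                "aa",
                "codon",
                "rscu_high",
                "rscu_low",
                "chi2",
                "p",
                "tier",
                "flag",
                "small_sample",
            ],
        )
    else:
        diagnostics.append("codon catalog skipped: too few genes with CAI")

    pr2_rows = []
    for r in kept:
        point = pr2_biases(tables[r.gene_id])
        pr2_rows.append((r.gene_id, r.category, point.gc_bias, point.au_bias))
    pr2_df = pd.DataFrame(pr2_rows, columns=["gene_id", "category", "gc_bias", "au_bias"])

    try:
        fit = neutrality_fit(profiles)
        neutrality = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "relative_neutrality_pct": fit.relative_neutrality_pct,
            "spearman_r": fit.spearman_r,
            "p_value": fit.p_value,
            "n_genes": fit.n_genes,
        }
    except ValueError as exc:
        neutrality = {"error": str(exc)}
        diagnostics.append(f"neutrality fit skipped: {exc}")

    enc_df = enc_plot_points(profiles)

    coa_rows = coa_cols = coa_inertia = axis_corr = None
    if len(kept) >= 2:
        matrix = build_rscu_matrix(
            [tables[r.gene_id] for r in kept], ids=[r.gene_id for r in kept]
        )
        gc3s_vec = [p.gc3s if p.gc3s is not None else np.nan for p in profiles]
        result = correspondence_analysis(matrix, config.n_axes, orient_by=gc3s_vec)
        coa_rows = result.row_scores.reset_index(names="gene_id")
        coa_cols = result.col_scores.reset_index(names="codon")
        coa_inertia = pd.DataFrame(
            {
                "axis": [f"Axis{i + 1}" for i in range(len(result.inertia_fraction))],
                "inertia_fraction": result.inertia_fraction,
            }
        )
        if result.n_axes > 0:
            axis_corr = axis_correlations(result, profiles)
    else:
        diagnostics.append("correspondence analysis skipped: fewer than 2 genes")

    try:
        sp_r, sp_p = spearman_matrix(profiles)
    except ValueError:
        sp_r = sp_p = None
        diagnostics.append("correlation matrix skipped: fewer than 3 genes")

    manifest = {
        "package": "cubkit",
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "n_input": len(records),
        "n_retained": len(kept),
        "excluded_short": [list(t) for t in report.excluded],
        "cai_reference": ref.provenance,
        "diagnostics": diagnostics,
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_tsv(prof_df, out / "profiles.tsv")
        write_tsv(rscu_df, out / "rscu.tsv")
        write_tsv(pr2_df, out / "pr2.tsv")
        write_tsv(enc_df, out / "encplot.tsv")
        write_tsv(
            pd.DataFrame([neutrality]), out / "neutrality.tsv"
        )
        if catalog_df is not None:
            write_tsv(catalog_df, out / "catalog.tsv")
        if sp_r is not None:
            write_tsv(sp_r.reset_index(names="variable"), out / "spearman_r.tsv")
            write_tsv(sp_p.reset_index(names="variable"), out / "spearman_p.tsv")
        if coa_rows is not None:
            write_tsv(coa_rows, out / "coa_rows.tsv")
            write_tsv(coa_cols, out / "coa_cols.tsv")
            write_tsv(coa_inertia, out / "coa_inertia.tsv")
        if axis_corr is not None:
            write_tsv(axis_corr, out / "axis_correlations.tsv")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8"
        )

    return PipelineResult(
        profiles=profiles,
        profile_table=prof_df,
        rscu_pooled=rscu_df,
        catalog=catalog_df,
        pr2_table=pr2_df,
        neutrality=neutrality,
        enc_plot=enc_df,
        coa_rows=coa_rows,
        coa_inertia=coa_inertia,
        axis_corr=axis_corr,
        manifest=manifest,
    )
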