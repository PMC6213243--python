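"""Contrast the neutrality-plot signatures of mutation and selection.

Two synthetic datasets: one where mutational pressure drives all codon
positions together (P12 linearly linked to P3), one where the third
position is decoupled from the mutational parameter.  The regression of
P12 on P3 separates the regimes: the mutation regime recovers the
generating slope, the selection regime is nearly flat.
"""

from cubkit import (
    CodonCountTable,
    cai_reference,
    count_codons,
    gene_index_profile,
    neutrality_fit,
)
from cubkit.synthetic_data import SimulationConfig, simulate_dataset

for regime in ("mutation", "selection"):
    cfg = SimulationConfig(
        n_genes=500, codons_per_gene=300, regime=regime, gc3_pressure=0.3, seed=42
    )
    records, _ = simulate_dataset(cfg)
    ref = cai_reference(CodonCountTable.pool([count_codons(r) for r in records[:30]]))
    profiles = [gene_index_profile(r, ref) for r in records]
    fit = neutrality_fit(profiles)
    print(
        f"{regime:>9} regime: slope={fit.slope:+.3f} "
        f"(relative neutrality {fit.relative_neutrality_pct:+.1f}%), "
        f"Spearman r={fit.spearman_r:+.3f}, p={fit.p_value:.2g}"
    )

print("\nmutation regime generates p12 = 0.20 + 0.50*p3 + noise, so the")
print("fitted slope should sit near 0.50; the selection regime decouples")
print("P3 from the mutational parameter, so its slope collapses toward 0.")
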