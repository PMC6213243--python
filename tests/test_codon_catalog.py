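import math

import numpy as np
import pytest

from cubkit import (
    CodonCountTable,
    cai_reference,
    count_codons,
    expression_extremes,
    gene_index_profile,
    optimal_codons,
    preferred_codons,
    rare_codons,
    rscu,
)
from cubkit.codon_catalog import ExpressionExtremes, _chi2_2x2
from cubkit.synthetic_data import SimulationConfig, simulate_dataset


class TestPreferredRare:
    def test_preferred_strictly_above_one(self):
        table = rscu(CodonCountTable({"GAU": 8, "GAC": 2}))
        assert preferred_codons(table) == {"GAU"}

    def test_even_usage_nothing_called(self, even_counts):
        table = rscu(even_counts)
        assert preferred_codons(table) == set()
        assert rare_codons(table) == set()

    def test_rare_threshold(self):
        table = rscu(CodonCountTable({"GAU": 99, "GAC": 1}))
        assert rare_codons(table) == {"GAC"}  # RSCU 0.02

    def test_unused_codon_of_populated_family_is_rare(self):
        table = rscu(CodonCountTable({"GUU": 5, "GUA": 5}))
        assert {"GUC", "GUG"} <= rare_codons(table)


def _profiles_with_cai(cais):
    class P:
        def __init__(self, gene_id, cai):
            self.gene_id, self.cai = gene_id, cai

    return [P(f"g{i:03d}", c) for i, c in enumerate(cais)]


def _tables_for(profiles):
    return {p.gene_id: CodonCountTable({"GAU": 1}, (p.gene_id,)) for p in profiles}


class TestExpressionExtremes:
    def test_five_percent_of_57_is_3(self):
        profiles = _profiles_with_cai(np.linspace(0.1, 0.9, 57))
        ext = expression_extremes(profiles, _tables_for(profiles), 0.05)
        assert len(ext.high_ids) == len(ext.low_ids) == math.ceil(0.05 * 57) == 3
        assert not set(ext.high_ids) & set(ext.low_ids)

    def test_minimum_one_gene_per_tail(self):
        profiles = _profiles_with_cai([0.2, 0.8])
        ext = expression_extremes(profiles, _tables_for(profiles), 0.05)
        assert len(ext.high_ids) == len(ext.low_ids) == 1
        assert ext.high_ids == ("g001",) and ext.low_ids == ("g000",)

    def test_ties_broken_by_gene_id(self):
        profiles = _profiles_with_cai([0.5] * 40)
        with pytest.warns(UserWarning):
            ext = expression_extremes(profiles, _tables_for(profiles), 0.05)
        assert ext.tied
        assert ext.low_ids == ("g000", "g001")
        assert set(ext.high_ids) == {"g038", "g039"}

    def test_fraction_bounds(self):
        profiles = _profiles_with_cai([0.2, 0.8])
        with pytest.raises(ValueError):
            expression_extremes(profiles, _tables_for(profiles), 0.6)

    def test_pooled_counts_are_sums(self):
        profiles = _profiles_with_cai([0.1, 0.5, 0.9])
        ext = expression_extremes(profiles, _tables_for(profiles), 0.05)
        assert ext.high_counts["GAU"] == 1 == ext.low_counts["GAU"]


class TestOptimalCodons:
    def _extremes(self, high, low):
        return ExpressionExtremes(
            high_ids=("h",),
            low_ids=("l",),
            fraction=0.05,
            high_counts=CodonCountTable(high),
            low_counts=CodonCountTable(low),
        )

    def test_hand_computed_chi2(self):
        chi2, p = _chi2_2x2(30, 10, 10, 30)
        assert chi2 == pytest.approx(20.0)
        assert p < 0.01

    def test_enrichment_called_strong(self):
        calls = optimal_codons(
            self._extremes({"GAU": 30, "GAC": 10}, {"GAU": 10, "GAC": 30})
        )
        by_codon = {c.codon: c for c in calls}
        assert by_codon["GAU"].tier == "strong"
        assert by_codon["GAU"].chi2 == pytest.approx(20.0)
        assert by_codon["GAU"].flag == "*"

    def test_identical_usage_not_called(self):
        calls = optimal_codons(
            self._extremes({"GAU": 30, "GAC": 10}, {"GAU": 30, "GAC": 10})
        )
        assert all(c.tier == "none" for c in calls)
        assert all(c.chi2 == 0.0 for c in calls)

    def test_directionality_rule(self):
        # GAC is massively enriched in the LOW set: significant but not optimal
        calls = optimal_codons(
            self._extremes({"GAU": 30, "GAC": 10}, {"GAU": 10, "GAC": 30})
        )
        by_codon = {c.codon: c for c in calls}
        assert by_codon["GAC"].p < 0.01
        assert by_codon["GAC"].tier == "none"

    def test_family_absent_from_one_tail_skipped(self):
        calls = optimal_codons(self._extremes({"GAU": 30}, {"UUU": 30}))
        assert calls == []

    def test_tail_order_invariance(self):
        profiles = _profiles_with_cai([0.1, 0.2, 0.8, 0.9])
        tables = {
            "g000": CodonCountTable({"GAU": 5, "GAC": 20}, ("g000",)),
            "g001": CodonCountTable({"GAU": 5, "GAC": 15}, ("g001",)),
            "g002": CodonCountTable({"GAU": 22, "GAC": 5}, ("g002",)),
            "g003": CodonCountTable({"GAU": 18, "GAC": 5}, ("g003",)),
        }
        ext = expression_extremes(profiles, tables, 0.4)
        ext_swapped = ExpressionExtremes(
            high_ids=ext.high_ids[::-1],
            low_ids=ext.low_ids[::-1],
            fraction=ext.fraction,
            high_counts=ext.high_counts,
            low_counts=ext.low_counts,
        )
        calls_a = {(c.codon, c.tier) for c in optimal_codons(ext)}
        calls_b = {(c.codon, c.tier) for c in optimal_codons(ext_swapped)}
        assert calls_a == calls_b


class TestRecoverySimulation:
    def test_designated_preferred_codons_recovered(self, code):
        """Expression-linked selection that doubles the odds of designated
        codons at full expression must be recovered by the CAI-tail
        chi-squared contrast with >= 90% sensitivity and precision."""
        preferred = frozenset(
            code.families[aa][0] for aa in code.amino_acids if aa not in "MW"
        )
        cfg = SimulationConfig(
            n_genes=200,
            codons_per_gene=300,
            regime="mixed",
            selection_strength=1.0,  # multiplier 1 + s*e reaches 2 at e = 1
            preferred_set=preferred,
            expression="uniform",
            seed=5,
        )
        records, _ = simulate_dataset(cfg)
        tables = {r.gene_id: count_codons(r) for r in records}
        ref = cai_reference(CodonCountTable.pool(list(tables.values())))
        profiles = [gene_index_profile(r, ref) for r in records]
        ext = expression_extremes(profiles, tables, 0.05)
        called = {c.codon for c in optimal_codons(ext) if c.tier != "none"}
        tp = len(called & preferred)
        assert tp / len(preferred) >= 0.9  # sensitivity
        assert tp / len(called) >= 0.9  # precision
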