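import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit import (
    CaiReference,
    CodonCountTable,
    cai,
    cai_reference,
    count_codons,
    enc,
    gc3s,
    gravy,
    aromo,
    rscu,
)
from cubkit.indices import family_homozygosity
from cubkit.synthetic_data import SimulationConfig, simulate_dataset


class TestRscu:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"GAU": 5, "GAC": 5}, {"GAU": 1.0, "GAC": 1.0}),
            ({"GAU": 8, "GAC": 2}, {"GAU": 1.6, "GAC": 0.4}),
            ({"AAU": 8, "AAC": 2}, {"AAU": 1.6, "AAC": 0.4}),  # 4:1 Asn pattern
        ],
    )
    def test_two_codon_families(self, counts, expected):
        table = rscu(CodonCountTable(counts))
        for codon, value in expected.items():
            assert table[codon] == pytest.approx(value)

    def test_absent_family_flagged_undefined(self):
        table = rscu(CodonCountTable({"GAU": 1}))
        assert "F" in table.undefined_families
        assert "UUU" not in table.rscu

    def test_stop_family_included(self):
        table = rscu(CodonCountTable({"UAA": 3}))
        assert table["UAA"] == pytest.approx(3.0)
        assert table["UAG"] == 0.0

    def test_met_trp_unity(self):
        table = rscu(CodonCountTable({"AUG": 7, "UGG": 2}))
        assert table["AUG"] == 1.0 and table["UGG"] == 1.0

    @given(
        counts=st.dictionaries(
            st.sampled_from(
                ["GCU", "GCC", "GCA", "GCG", "CGU", "CGC", "CGA", "CGG", "AGA",
                 "AGG", "UUU", "UUC", "AUG"]
            ),
            st.integers(min_value=0, max_value=50),
            min_size=1,
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_family_sum_conservation(self, counts, code):
        table = rscu(CodonCountTable(counts))
        for aa, family in code.families.items():
            if aa in table.undefined_families:
                continue
            if any(c in table.rscu for c in family):
                assert sum(table[c] for c in family) == pytest.approx(len(family))


class TestEnc:
    def test_extreme_bias_is_20(self, one_codon_per_aa_counts):
        assert enc(one_codon_per_aa_counts) == 20.0

    def test_even_usage_capped_at_61(self, even_counts):
        assert enc(even_counts) == 61.0

    def test_single_two_fold_family_homozygosity(self, code):
        # counts {3,1}: F = (4 * 0.625 - 1) / 3 = 0.5
        f = family_homozygosity(CodonCountTable({"GAU": 3, "GAC": 1}), code.families["D"])
        assert f == pytest.approx(0.5)

    def test_incomplete_classes_give_missing(self):
        assert enc(CodonCountTable({"GAU": 3, "GAC": 1})) is None

    def test_ile_imputation_path(self, code, one_codon_per_aa_counts):
        # removing the Ile family entirely still yields an ENc via the
        # (F2+F4)/2 imputation; with every F = 1 the value stays 20
        counts = dict(one_codon_per_aa_counts.counts)
        for c in code.families["I"]:
            counts.pop(c, None)
        assert enc(CodonCountTable(counts)) == pytest.approx(20.0)

    def test_scale_invariance_large_n(self, code):
        # Wright's F-hat carries an O(1/n) finite-sample term per family, so
        # scale invariance is a large-n limit: use family counts in the
        # thousands, where doubling every count moves ENc by < 0.05
        rng = np.random.default_rng(17)
        counts = {c: int(rng.integers(500, 2000)) for c in code.sense_codons}
        t = CodonCountTable(counts)
        doubled = CodonCountTable({c: 2 * n for c, n in counts.items()})
        assert abs(enc(t) - enc(doubled)) < 0.05

    def test_monotone_in_selection_strength(self, code):
        preferred = frozenset(
            code.families[aa][0] for aa in code.amino_acids if aa not in "MW"
        )
        means = []
        for s in (0.0, 0.5, 1.0, 2.0, 4.0):
            cfg = SimulationConfig(
                n_genes=30,
                codons_per_gene=500,
                regime="mixed",
                selection_strength=s,
                preferred_set=preferred,
                seed=11,
            )
            records, _ = simulate_dataset(cfg)
            means.append(np.mean([enc(count_codons(r)) for r in records]))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestCai:
    def test_reference_w_ratio(self):
        ref = cai_reference(CodonCountTable({"UUU": 9, "UUC": 1}))
        assert ref.w["UUU"] == 1.0
        assert ref.w["UUC"] == pytest.approx(1 / 9)

    def test_even_reference_all_w_one(self, even_counts):
        ref = cai_reference(even_counts)
        assert all(w == 1.0 for w in ref.w.values())

    def test_absent_codon_gets_floor(self):
        ref = cai_reference(CodonCountTable({"UUU": 10}))
        assert ref.w["UUC"] == 0.01

    def test_met_trp_stop_excluded_from_w(self, even_counts):
        ref = cai_reference(even_counts)
        assert not {"AUG", "UGG", "UAA", "UAG", "UGA"} & set(ref.w)

    def test_constant_w_gene(self):
        ref = cai_reference(CodonCountTable({"UUU": 9, "UUC": 1}))
        assert cai(CodonCountTable({"UUC": 10}), ref) == pytest.approx(1 / 9)

    def test_maximal_iff_only_preferred(self, even_counts):
        ref = cai_reference(CodonCountTable({"UUU": 9, "UUC": 1, "GAU": 5, "GAC": 5}))
        assert cai(CodonCountTable({"UUU": 4, "GAU": 2, "GAC": 1}), ref) == 1.0
        assert cai(CodonCountTable({"UUU": 4, "UUC": 1}), ref) < 1.0

    def test_unscorable_gene_missing(self):
        ref = cai_reference(CodonCountTable({"UUU": 9, "UUC": 1}))
        assert cai(CodonCountTable({"AUG": 5}), ref) is None

    def test_tsv_round_trip(self, tmp_path):
        ref = cai_reference(CodonCountTable({"UUU": 9, "UUC": 1}))
        path = tmp_path / "ref.tsv"
        ref.to_tsv(path)
        back = CaiReference.from_tsv(path)
        assert back.w.keys() == dict(ref.w).keys()
        for c in ref.w:
            assert back.w[c] == pytest.approx(ref.w[c], rel=1e-4)


class TestGc3s:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"GCG": 4}, 1.0),
            ({"GCA": 4}, 0.0),
            ({"GCG": 2, "GCA": 2}, 0.5),
        ],
    )
    def test_small_tables(self, counts, expected):
        assert gc3s(CodonCountTable(counts)) == expected

    def test_ile_included_but_stops_met_trp_not(self):
        # distinct from P3: AUA counts here, AUG/UGG/stops never do
        assert gc3s(CodonCountTable({"AUA": 1, "GCG": 1})) == 0.5
        assert gc3s(CodonCountTable({"AUG": 5, "UGG": 5, "UAA": 5})) is None


class TestProteinIndices:
    def test_gravy_table_values(self):
        assert gravy("GGGG") == pytest.approx(-0.4)
        assert gravy("III") == pytest.approx(4.5)
        assert gravy("GI") == pytest.approx(2.05)

    def test_aromo(self):
        assert aromo("FFFF") == 1.0
        assert aromo("GAVL") == 0.0
        assert aromo("FYGA") == 0.5

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            gravy("")
        with pytest.raises(ValueError):
            aromo("")
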