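import numpy as np
import pandas as pd
import pytest

from cubkit import (
    CodonCountTable,
    axis_correlations,
    build_rscu_matrix,
    cai_reference,
    correspondence_analysis,
    count_codons,
    degrees_of_freedom,
    gene_index_profile,
    informative_codons,
)
from cubkit.coa import CoaResult
from cubkit.synthetic_data import SimulationConfig, simulate_dataset


class TestInformativeCodons:
    def test_59_codons_41_dof(self, code):
        codons = informative_codons(code)
        assert len(codons) == 59
        assert not {"AUG", "UGG", "UAA", "UAG", "UGA"} & set(codons)
        # 59 codons in 18 multi-codon families
        assert degrees_of_freedom(code) == 59 - 18 == 41


class TestRscuMatrix:
    def test_shape_and_fill(self):
        g1 = CodonCountTable({"GAU": 3, "GAC": 1}, ("g1",))
        g2 = CodonCountTable({"UUU": 2, "UUC": 2}, ("g2",))
        m = build_rscu_matrix([g1, g2])
        assert m.shape == (2, 59)
        assert m.loc["g1", "GAU"] == pytest.approx(1.5)
        # family absent from a gene: zero-filled
        assert m.loc["g1", "UGU"] == 0.0 and m.loc["g1", "UGC"] == 0.0

    def test_identical_usage_identical_rows(self):
        g1 = CodonCountTable({"GAU": 3, "GAC": 1}, ("g1",))
        g2 = CodonCountTable({"GAU": 30, "GAC": 10}, ("g2",))
        m = build_rscu_matrix([g1, g2])
        assert np.allclose(m.loc["g1"], m.loc["g2"])

    def test_needs_two_genes(self):
        with pytest.raises(ValueError):
            build_rscu_matrix([CodonCountTable({"GAU": 1})])


def _random_matrix(n=5, k=6, seed=3):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.random((n, k)) * 4,
        index=[f"g{i}" for i in range(n)],
        columns=[f"c{j}" for j in range(k)],
    )


class TestCorrespondenceAnalysis:
    def test_matches_independent_implementation(self):
        from skbio.stats.ordination import ca as skbio_ca

        X = _random_matrix()
        mine = correspondence_analysis(X, n_axes=4)
        other = skbio_ca(X, scaling=1)
        assert np.allclose(
            mine.inertia_fraction[:4], other.proportion_explained.values[:4]
        )
        for a in range(4):
            assert np.allclose(
                np.abs(mine.row_scores.values[:, a]),
                np.abs(other.samples.values[:, a]),
            )

    def test_2x2_chi_square_decomposition(self):
        # one non-trivial axis; total inertia equals chi2/n computed by hand
        X = pd.DataFrame([[30.0, 10.0], [10.0, 30.0]])
        res = correspondence_analysis(X)
        chi2 = 80 * (30 * 30 - 10 * 10) ** 2 / (40**4)
        assert res.total_inertia == pytest.approx(chi2 / 80)
        assert res.inertia_fraction == pytest.approx([1.0])

    def test_reconstruction_from_singular_triplets(self):
        # the standardized residual matrix equals the sum of its triplets
        X = _random_matrix(5, 6, seed=8)
        A = X.to_numpy()
        P = A / A.sum()
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        res = correspondence_analysis(X, n_axes=6)
        # rebuild S from principal coordinates: S = sum_a (sqrt(r) f_a)(sqrt(c) g_a)^T / sigma_a
        sv = np.sqrt(res.inertia_fraction * res.total_inertia)
        rebuilt = np.zeros_like(S)
        for a in range(res.n_axes):
            f = res.row_scores.values[:, a] * np.sqrt(r)
            g = res.col_scores.values[:, a] * np.sqrt(c)
            rebuilt += np.outer(f, g) / sv[a]
        assert np.allclose(rebuilt, S, atol=1e-10)

    def test_proportional_rows_zero_inertia(self):
        X = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [0.5, 1.0, 1.5]])
        res = correspondence_analysis(X)
        assert res.total_inertia == 0.0
        assert res.n_axes == 0

    def test_duplicated_gene_rows_get_identical_scores(self):
        X = _random_matrix(4, 6, seed=1)
        X2 = pd.concat([X, X.iloc[[0]].rename(index={"g0": "g0dup"})])
        res = correspondence_analysis(X2, n_axes=3)
        assert np.allclose(res.row_scores.loc["g0"], res.row_scores.loc["g0dup"])

    def test_scalar_invariance(self):
        X = _random_matrix()
        a = correspondence_analysis(X, n_axes=3)
        b = correspondence_analysis(X * 7.3, n_axes=3)
        assert np.allclose(np.abs(a.row_scores), np.abs(b.row_scores))
        assert np.allclose(a.inertia_fraction, b.inertia_fraction)

    def test_inertia_fractions_sum_to_one(self):
        res = correspondence_analysis(_random_matrix(7, 9, seed=5))
        assert res.inertia_fraction.sum() == pytest.approx(1.0)
        assert (res.inertia_fraction >= 0).all()

    def test_orientation_deterministic(self):
        X = _random_matrix()
        ov = np.arange(5)
        a = correspondence_analysis(X, orient_by=ov)
        b = correspondence_analysis(X, orient_by=ov)
        assert np.allclose(a.row_scores, b.row_scores)
        # orientation rule: non-negative rank correlation with the covariate
        from scipy.stats import spearmanr

        for axis in a.row_scores.columns:
            r = spearmanr(a.row_scores[axis], ov).statistic
            assert r >= 0 or np.isclose(r, 0)


@pytest.fixture(scope="module")
def gc3_driven_dataset():
    """Genes whose codon usage varies along a third-position GC gradient."""
    cfg = SimulationConfig(n_genes=80, codons_per_gene=400, regime="mutation", seed=13)
    records, _ = simulate_dataset(cfg)
    tables = [count_codons(r) for r in records]
    ref = cai_reference(CodonCountTable.pool(tables))
    profiles = [gene_index_profile(r, ref) for r in records]
    matrix = build_rscu_matrix(tables, ids=[r.gene_id for r in records])
    return matrix, profiles


class TestAxisCorrelations:
    def test_gc3_gradient_loads_axis1(self, gc3_driven_dataset):
        matrix, profiles = gc3_driven_dataset
        gc3 = [p.gc3s for p in profiles]
        res = correspondence_analysis(matrix, orient_by=gc3)
        table = axis_correlations(res, profiles)
        r_axis1 = table.query("axis == 'Axis1' and index == 'gc3s'").iloc[0]
        assert r_axis1.r > 0.8  # composition is the dominant factor
        assert r_axis1.tier == "*"

    def test_sign_flip_invariance(self, gc3_driven_dataset):
        matrix, profiles = gc3_driven_dataset
        res = correspondence_analysis(matrix)
        flipped = CoaResult(
            row_scores=-res.row_scores,
            col_scores=-res.col_scores,
            inertia_fraction=res.inertia_fraction,
            total_inertia=res.total_inertia,
            n_codons=res.n_codons,
            dof=res.dof,
        )
        a = axis_correlations(res, profiles)
        b = axis_correlations(flipped, profiles)
        assert np.allclose(np.abs(a.r), np.abs(b.r), equal_nan=True)

    def test_axis_against_itself(self, gc3_driven_dataset):
        matrix, profiles = gc3_driven_dataset
        res = correspondence_analysis(matrix)
        scores = dict(zip(res.row_scores.index, res.row_scores["Axis1"]))
        for p in profiles:
            p.cai = scores[p.gene_id]  # plant the axis as an index
        table = axis_correlations(res, profiles, variables=("cai",))
        assert table.query("axis == 'Axis1'").iloc[0].r == pytest.approx(1.0)

    def test_mismatched_gene_sets_rejected(self, gc3_driven_dataset):
        matrix, profiles = gc3_driven_dataset
        res = correspondence_analysis(matrix)
        with pytest.raises(ValueError):
            axis_correlations(res, profiles[:10])
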