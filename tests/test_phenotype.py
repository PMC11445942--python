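"""Embedding, k-means and internal-validity scores vs definitional oracles."""

import numpy as np
import pandas as pd
import pytest

from arfpheno.phenotype import (
    PhenotypeModel,
    cluster_kmeans,
    fit_embedding,
    model_select,
)


# --- definitional oracles (exhaustive pairwise computation, tiny n) ---------

def oracle_silhouette(x, labels):
    n = len(x)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    s = []
    for i in range(n):
        own = labels[i]
        same = [j for j in range(n) if labels[j] == own and j != i]
        if not same:
            s.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == other])
            for other in set(labels) if other != own
        )
        s.append((b - a) / max(a, b))
    return float(np.mean(s))


def oracle_calinski_harabasz(x, labels):
    n, k = len(x), len(set(labels))
    mean = x.mean(axis=0)
    bg = sum((labels == g).sum() * ((x[labels == g].mean(axis=0) - mean) ** 2).sum()
             for g in set(labels))
    wg = sum(((x[labels == g] - x[labels == g].mean(axis=0)) ** 2).sum()
             for g in set(labels))
    return float((bg / (k - 1)) / (wg / (n - k)))


def oracle_davies_bouldin(x, labels):
    groups = sorted(set(labels))
    cents = {g: x[labels == g].mean(axis=0) for g in groups}
    scatter = {
        g: np.mean(np.linalg.norm(x[labels == g] - cents[g], axis=1)) for g in groups
    }
    ratios = []
    for g in groups:
        ratios.append(max(
            (scatter[g] + scatter[h]) / np.linalg.norm(cents[g] - cents[h])
            for h in groups if h != g
        ))
    return float(np.mean(ratios))


def test_validity_scores_match_oracles_on_random_tiny_instances():
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_score,
    )

    rng = np.random.default_rng(12)
    for _ in range(100):
        n = int(rng.integers(5, 13))
        x = rng.normal(size=(n, 2))
        labels = rng.integers(0, 2, size=n)
        while len(set(labels)) < 2:
            labels = rng.integers(0, 2, size=n)
        assert np.isclose(silhouette_score(x, labels), oracle_silhouette(x, labels),
                          rtol=1e-7, atol=1e-10)
        assert np.isclose(calinski_harabasz_score(x, labels),
                          oracle_calinski_harabasz(x, labels), rtol=1e-7)
        assert np.isclose(davies_bouldin_score(x, labels),
                          oracle_davies_bouldin(x, labels), rtol=1e-7)


# --- embedding --------------------------------------------------------------

class TestEmbedding:
    def test_pca_full_rank_is_lossless(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(50, 5)))
        emb, _ = fit_embedding(x, "pca", 4, seed=0)
        full, _ = fit_embedding(x, "pca", 5, seed=0) if False else (None, None)
        emb5, _ = fit_embedding(pd.concat([x, x.iloc[:, :1] * 0 + 1], axis=1), "pca", 5, seed=0)
        # rank-5 data embedded in 5 of 6 dims (one constant col) is lossless
        assert emb5.reconstruction_mse <= 1e-9

    def test_pca_dimension_one_on_a_line(self):
        t = np.linspace(0, 1, 30)
        x = pd.DataFrame({"a": 2 * t, "b": -3 * t})
        emb, _ = fit_embedding(x, "pca", 1, seed=0)
        assert emb.reconstruction_mse <= 1e-9

    def test_pca_mse_non_increasing_in_dimension(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(80, 6)))
        mses = [fit_embedding(x, "pca", d, seed=0)[0].reconstruction_mse
                for d in (1, 2, 3, 4, 5)]
        assert all(m2 <= m1 + 1e-12 for m1, m2 in zip(mses, mses[1:]))
        # cross-check against the cumulative-explained-variance identity
        total_var = x.var(ddof=0).sum()
        from sklearn.decomposition import PCA

        pca = PCA(n_components=5).fit(x.to_numpy())
        for d, m in zip((1, 2, 3, 4, 5), mses):
            residual = total_var - pca.explained_variance_[:d].sum() * (len(x) - 1) / len(x)
            assert np.isclose(m * x.shape[1], residual, rtol=1e-8)

    def test_dimension_must_be_below_feature_count(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError, match="dimension"):
            fit_embedding(x, "pca", 3, seed=0)

    def test_umap_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(60, 5)))
        _, c1 = fit_embedding(x, "umap", 2, seed=5, mse_subsample=10)
        _, c2 = fit_embedding(x, "umap", 2, seed=5, mse_subsample=10)
        assert np.allclose(c1, c2)


# --- clustering -------------------------------------------------------------

def two_blobs(n=40, sep=50.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, 2))
    b = rng.normal(size=(n, 2)) + sep
    return np.vstack([a, b]), np.array([0] * n + [1] * n)


class TestKMeans:
    def test_separated_blobs_recovered(self):
        x, truth = two_blobs()
        res = cluster_kmeans(x, 2, seed=0)
        assert res.silhouette > 0.9
        # one-to-one mapping between assignments and blob identity
        assert len(set(zip(res.assignments, truth))) == 2

    def test_identical_points_degenerate(self):
        x = np.ones((10, 2))
        with pytest.raises(ValueError, match="distinct"):
            cluster_kmeans(x, 2, seed=0)

    def test_same_seed_identical_assignments(self):
        x, _ = two_blobs(seed=3)
        r1 = cluster_kmeans(x, 2, seed=1)
        r2 = cluster_kmeans(x, 2, seed=1)
        assert np.array_equal(r1.assignments, r2.assignments)

    def test_row_permutation_invariant_labelling(self):
        x, _ = two_blobs(seed=4)
        perm = np.random.default_rng(0).permutation(len(x))
        r1 = cluster_kmeans(x, 2, seed=1)
        r2 = cluster_kmeans(x[perm], 2, seed=1)
        assert np.array_equal(r1.assignments[perm], r2.assignments)

    def test_inertia_non_increasing_in_n_init(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(100, 2)) * [1, 5]
        prev = np.inf
        for n_init in (1, 5, 20):
            res = cluster_kmeans(x, 5, seed=0, n_init=n_init)
            assert res.inertia <= prev + 1e-9
            prev = res.inertia

    def test_k_out_of_range(self):
        x, _ = two_blobs(n=3)
        with pytest.raises(ValueError, match="k="):
            cluster_kmeans(x, 7, seed=0)


# --- model selection --------------------------------------------------------

def four_blobs(n_per=60, sep=25.0, p=6, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(4, p)) * sep
    x = np.vstack([c + rng.normal(size=(n_per, p)) for c in centers])
    labels = np.repeat(np.arange(4), n_per)
    return pd.DataFrame(x, index=[f"e{i}" for i in range(4 * n_per)]), labels


class TestModelSelect:
    def test_four_blob_cohort_selects_k4(self):
        x, truth = four_blobs()
        sel, table = model_select(x, methods=("pca",), dimensions=(2, 3),
                                  ks=(2, 3, 4, 5, 6), seed=0)
        assert sel["k"] == 4
        assert not sel["weak_structure"]
        assert len(table) == 2 * 5

    def test_single_blob_silhouette_low_and_flag_consistent(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(150, 5)))
        sel, table = model_select(x, methods=("pca",), dimensions=(2,),
                                  ks=(2, 3, 4), seed=0)
        best = table.sort_values(
            ["first_places", "silhouette"], ascending=False).iloc[0]
        assert best["silhouette"] < 0.4  # no real structure to find
        assert sel["weak_structure"] == bool(best["silhouette"] < 0.25)

    def test_single_combination_grid_returned(self):
        x, _ = four_blobs(n_per=30)
        sel, table = model_select(x, methods=("pca",), dimensions=(3,), ks=(4,), seed=0)
        assert (sel["method"], sel["dimension"], sel["k"]) == ("pca", 3, 4)
        assert len(table) == 1


class TestResultsObject:
    def test_fit_returns_results_with_stable_assignments(self):
        x, truth = four_blobs(n_per=40)
        res = PhenotypeModel(x, methods=("pca",), dimensions=(2,), ks=(3, 4, 5),
                             seed=0).fit()
        assert res.k == 4
        a = res.assign_phenotype_indices()
        assert set(a.index) == set(x.index)
        assert a.value_counts().size == 4
        # round-trip persist/load
        import io

        buf = io.StringIO()
        a.to_csv(buf)
        buf.seek(0)
        back = pd.read_csv(buf, index_col=0)["cluster"]
        assert (back.loc[a.index] == a).all()
        assert "silhouette" in res.summary()

    def test_incomplete_matrix_rejected(self):
        x = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(ValueError, match="complete"):
            PhenotypeModel(x)
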