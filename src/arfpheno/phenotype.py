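"""Unsupervised phenotype derivation: embedding, k-means, model selection.

The central estimation object follows the fitted-model idiom: a
``PhenotypeModel`` is built from a scaled feature matrix; ``fit()`` searches
a (method, dimension, k) grid, scores every combination with the three
internal-validity indices plus reconstruction error, and returns a
``PhenotypeResults`` carrying the chosen configuration, assignments,
embedding coordinates and the full auditable score table.

Selection rule: each combination is ranked on silhouette (higher better),
Calinski-Harabasz (higher better) and Davies-Bouldin (lower better); the
combination holding the most first places wins, ties broken by silhouette,
then smaller k, then smaller dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

WEAK_SILHOUETTE = 0.25


@dataclass
class EmbeddingModel:
    method: str  # "umap" or "pca"
    dimension: int
    seed: int
    estimator: object
    reconstruction_mse: float

    def transform(self, scaled: np.ndarray) -> np.ndarray:
        return self.estimator.transform(scaled)


@dataclass
class ClusteringResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    silhouette: float
    calinski_harabasz: float
    davies_bouldin: float
    inertia: float


def fit_embedding(scaled: pd.DataFrame | np.ndarray, method: str, dimension: int,
                  seed: int = 0, mse_subsample: int = 200,
                  umap_kwargs: dict | None = None) -> tuple[EmbeddingModel, np.ndarray]:
    """Fit a UMAP or PCA embedding and estimate reconstruction MSE.

    PCA reconstruction uses the exact linear back-projection; UMAP uses the
    method's iterative inverse mapping, evaluated on a seeded subsample of
    ``mse_subsample`` points to bound run time.
    """
    x = np.asarray(scaled, dtype=float)
    n, p = x.shape
    if dimension >= p:
        raise ValueError(f"embedding dimension {dimension} must be < feature count {p}")
    if dimension < 1:
        raise ValueError("embedding dimension must be >= 1")
    if method == "pca":
        est = PCA(n_components=dimension, random_state=seed)
        coords = est.fit_transform(x)
        recon = est.inverse_transform(coords)
        mse = float(np.mean((recon - x) ** 2))
    elif method == "umap":
        import umap

        kw = dict(n_neighbors=15, min_dist=0.1, metric="euclidean")
        if umap_kwargs:
            kw.update(umap_kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = umap.UMAP(n_components=dimension, random_state=seed, **kw)
            coords = est.fit_transform(x)
            rng = np.random.default_rng(seed)
            take = rng.choice(n, size=min(mse_subsample, n), replace=False)
            recon = est.inverse_transform(coords[take])
        mse = float(np.mean((recon - x[take]) ** 2))
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    model = EmbeddingModel(method=method, dimension=dimension, seed=seed,
                           estimator=est, reconstruction_mse=mse)
    return model, coords


def cluster_kmeans(coords: np.ndarray, k: int, seed: int = 0,
                   n_init: int = 10) -> ClusteringResult:
    """Best-of-``n_init`` k-means with validity scores in embedding space."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 2 or k > n:
        raise ValueError(f"k={k} out of range for {n} points")
    if np.unique(coords, axis=0).shape[0] < k:
        raise ValueError("fewer distinct points than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(coords)
    # canonical cluster indices: order centroids lexicographically so the
    # labelling is invariant to input row order
    order = np.lexsort(km.cluster_centers_.T[::-1])
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centroids = km.cluster_centers_[order]
    return ClusteringResult(
        k=k,
        assignments=labels,
        centroids=centroids,
        silhouette=float(silhouette_score(coords, labels)),
        calinski_harabasz=float(calinski_harabasz_score(coords, labels)),
        davies_bouldin=float(davies_bouldin_score(coords, labels)),
        inertia=float(km.inertia_),
    )


def _rank_vote(table: pd.DataFrame) -> pd.DataFrame:
    tab = table.copy()
    tab["first_places"] = (
        (tab["silhouette"] == tab["silhouette"].max()).astype(int)
        + (tab["calinski_harabasz"] == tab["calinski_harabasz"].max()).astype(int)
        + (tab["davies_bouldin"] == tab["davies_bouldin"].min()).astype(int)
    )
    return tab


def model_select(
    scaled: pd.DataFrame,
    methods: tuple[str, ...] = ("umap",),
    dimensions: tuple[int, ...] = (2, 3, 4, 5),
    ks: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    seed: int = 0,
    n_init: int = 10,
    mse_subsample: int = 200,
) -> tuple[dict, pd.DataFrame]:
    """Score every (method, dimension, k); pick by rank vote. Returns
    (selection dict, full score table)."""
    rows = []
    cache: dict[tuple[str, int], tuple[EmbeddingModel, np.ndarray]] = {}
    for method in methods:
        for dim in dimensions:
            emb, coords = fit_embedding(scaled, method, dim, seed=seed,
                                        mse_subsample=mse_subsample)
            cache[(method, dim)] = (emb, coords)
            for k in ks:
                res = cluster_kmeans(coords, k, seed=seed, n_init=n_init)
                rows.append(
                    {
                        "method": method,
                        "dimension": dim,
                        "k": k,
                        "silhouette": res.silhouette,
                        "calinski_harabasz": res.calinski_harabasz,
                        "davies_bouldin": res.davies_bouldin,
                        "reconstruction_mse": emb.reconstruction_mse,
                    }
                )
    table = _rank_vote(pd.DataFrame(rows))
    best = table.sort_values(
        by=["first_places", "silhouette", "k", "dimension"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).iloc[0]
    sel = {
        "method": best["method"],
        "dimension": int(best["dimension"]),
        "k": int(best["k"]),
        "weak_structure": bool(best["silhouette"] < WEAK_SILHOUETTE),
    }
    return sel, table


class PhenotypeModel:
    """Unsupervised phenotype model over a scaled encounter x feature matrix."""

    def __init__(self, scaled: pd.DataFrame,
                 methods: tuple[str, ...] = ("umap",),
                 dimensions: tuple[int, ...] = (2, 3, 4, 5),
                 ks: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
                 seed: int = 0, n_init: int = 10, mse_subsample: int = 200):
        if scaled.isna().any().any():
            raise ValueError("scaled matrix must be complete")
        self.scaled = scaled
        self.methods = tuple(methods)
        self.dimensions = tuple(dimensions)
        self.ks = tuple(ks)
        self.seed = seed
        self.n_init = n_init
        self.mse_subsample = mse_subsample

    @classmethod
    def from_dataframe(cls, scaled: pd.DataFrame, **kwargs) -> "PhenotypeModel":
        return cls(scaled, **kwargs)

    def fit(self) -> "PhenotypeResults":
        sel, table = model_select(
            self.scaled, self.methods, self.dimensions, self.ks,
            seed=self.seed, n_init=self.n_init, mse_subsample=self.mse_subsample,
        )
        emb, coords = fit_embedding(
            self.scaled, sel["method"], sel["dimension"], seed=self.seed,
            mse_subsample=self.mse_subsample,
        )
        clus = cluster_kmeans(coords, sel["k"], seed=self.seed, n_init=self.n_init)
        return PhenotypeResults(self, sel, table, emb, coords, clus)


class PhenotypeResults:
    """Fitted phenotype derivation: selection, assignments, embedding."""

    def __init__(self, model: PhenotypeModel, selection: dict,
                 score_table: pd.DataFrame, embedding: EmbeddingModel,
                 coords: np.ndarray, clustering: ClusteringResult):
        self.model = model
        self.selection = selection
        self.score_table = score_table
        self.embedding = embedding
        self.coordinates = pd.DataFrame(
            coords, index=model.scaled.index,
            columns=[f"dim{i + 1}" for i in range(coords.shape[1])],
        )
        self.clustering = clustering
        self.assignments = pd.Series(
            clustering.assignments, index=model.scaled.index, name="cluster"
        )

    @property
    def k(self) -> int:
        return self.clustering.k

    @property
    def silhouette(self) -> float:
        return self.clustering.silhouette

    def assign_phenotype_indices(self) -> pd.Series:
        """Stable encounter_id -> cluster index mapping (persistable)."""
        return self.assignments.copy()

    def summary(self) -> str:
        s = self.selection
        lines = [
            "Phenotype derivation results",
            "=" * 60,
            f"method: {s['method']}  dimension: {s['dimension']}  k: {s['k']}",
            f"silhouette: {self.clustering.silhouette:.3f}   "
            f"Calinski-Harabasz: {self.clustering.calinski_harabasz:.1f}   "
            f"Davies-Bouldin: {self.clustering.davies_bouldin:.3f}",
            f"reconstruction MSE: {self.embedding.reconstruction_mse:.4f}",
            f"cluster sizes: {self.assignments.value_counts().sort_index().to_dict()}",
        ]
        if s.get("weak_structure"):
            lines.append("warning: weak cluster structure (silhouette < 0.25)")
        return "\n".join(lines)
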