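"""Phenotype discovery: UMAP embedding + HDBSCAN on the three totals.

The model ingests per-participant BAI, PHQ-9 and PCL-C totals,
standardizes them, embeds them with UMAP (nonlinear, topology
preserving) and clusters the embedding with HDBSCAN, which fixes neither
the number nor the shape of clusters and leaves low-density points in a
noise group.  Cluster quality is summarized by the mean silhouette over
clustered points, and clusters are mapped to phenotype names by a
deterministic rubric built around the PCL-C clinical threshold.

Usage::

    res = PhenotypeCluster(scored_df, seed=11).fit()
    res.summary()
    res.assignments()          # per-participant cluster + phenotype
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .instruments import PTSD_THRESHOLD

__all__ = [
    "EmbeddingConfig",
    "NOISE",
    "embed_scores",
    "cluster_embedding",
    "evaluate_silhouette",
    "label_phenotypes",
    "adjusted_rand",
    "PhenotypeCluster",
    "PhenotypeClusterResults",
]

#: Cluster id assigned to points in no dense region.
NOISE = -1

SCORE_COLUMNS = ("bai_total", "phq9_total", "pclc_total")


@dataclass
class EmbeddingConfig:
    """UMAP settings.

    Totals are z-scored first unless disabled.  ``dither`` is the
    half-width of seeded uniform noise added to the raw totals before
    standardization: questionnaire totals live on an integer lattice,
    and un-rounding them (half-width 0.5 restores exactly the mass the
    discretization removed) prevents duplicate-point artifacts in the
    neighbor graph and in density estimation.  Set to 0 for exact
    embedding of the recorded totals.
    """

    n_components: int = 2
    n_neighbors: int = 10
    min_dist: float = 0.0
    metric: str = "euclidean"
    seed: int = 0
    standardize_inputs: bool = True
    dither: float = 0.5

    def validate(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")


def embed_scores(score_matrix: np.ndarray, config: EmbeddingConfig) -> np.ndarray:
    """Embed an (n, 3) matrix of totals; deterministic given config.seed."""
    import umap  # deferred: numba compilation makes this import heavy

    config.validate()
    X = np.asarray(score_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("score matrix must be 2-dimensional")
    if np.isnan(X).any():
        raise ValueError("missing totals in the score matrix")
    if X.shape[0] <= config.n_neighbors:
        raise ValueError(
            f"n={X.shape[0]} too small for n_neighbors={config.n_neighbors}"
        )
    if np.ptp(X, axis=0).max() == 0:
        # degenerate input: all participants identical; there is nothing
        # to embed and UMAP's optimizer would scatter the duplicates
        return np.zeros((X.shape[0], config.n_components))
    if config.dither > 0:
        rng = np.random.default_rng(config.seed)
        X = X + rng.uniform(-config.dither, config.dither, X.shape)
    if config.standardize_inputs:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # a constant column carries no information
        X = (X - X.mean(axis=0)) / sd
    reducer = umap.UMAP(
        n_components=config.n_components,
        n_neighbors=config.n_neighbors,
        min_dist=config.min_dist,
        metric=config.metric,
        random_state=config.seed,
    )
    return np.asarray(reducer.fit_transform(X))


def cluster_embedding(
    embedding: np.ndarray,
    min_cluster_size: int,
    min_samples: int | None = None,
    selection_method: str = "leaf",
) -> np.ndarray:
    """HDBSCAN labels on the embedding; NOISE (-1) marks outliers.

    Leaf selection with a high ``min_samples`` extracts conservative
    cluster cores and sheds boundary points to noise, which is the
    behavior wanted when overlapping symptom profiles make cluster
    margins ambiguous.
    """
    X = np.asarray(embedding, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("embedding must be finite")
    clusterer = HDBSCAN(
        min_cluster_size=int(min_cluster_size),
        min_samples=int(min_samples if min_samples is not None else min_cluster_size),
        cluster_selection_method=selection_method,
        copy=True,
    )
    return clusterer.fit(X).labels_


def evaluate_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over non-noise points; needs >= 2 real clusters."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    mask = labels != NOISE
    kept = labels[mask]
    if len(np.unique(kept)) < 2:
        raise ValueError("silhouette undefined with fewer than 2 clusters")
    return float(silhouette_score(X[mask], kept))


def adjusted_rand(
    labels_true: np.ndarray, labels_pred: np.ndarray, ignore_noise: bool = True
) -> float:
    """ARI between a recovered partition and ground truth, excluding noise."""
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if ignore_noise:
        mask = p != NOISE
        t, p = t[mask], p[mask]
    return float(adjusted_rand_score(t, p))


def label_phenotypes(
    summaries: pd.DataFrame, ptsd_threshold: float = PTSD_THRESHOLD
) -> dict:
    """Deterministic phenotype names from per-cluster mean totals.

    Rubric: rank clusters by mean PCL-C descending; the first at or above
    the PTSD threshold is the PTSD phenotype.  Among the rest, the
    cluster with the lowest aggregate elevation (BAI + PHQ-9 + PCL-C
    above its floor of 17) is the minimal-symptom phenotype; when exactly
    two clusters remain, the higher-BAI one is the anxiety phenotype and
    the other the mixed anxiety/depression phenotype.  Any cluster the
    rubric cannot place is 'unlabeled' — never dropped.

    `summaries` is indexed by cluster id with columns
    ``bai_mean, phq9_mean, pclc_mean``.
    """
    names = {cl: "unlabeled" for cl in summaries.index}
    pool = summaries.sort_values("pclc_mean", ascending=False)
    rest = list(pool.index)
    for cl in rest:
        if pool.loc[cl, "pclc_mean"] >= ptsd_threshold:
            names[cl] = "ptsd"
            rest.remove(cl)
            break
    if rest:
        elevation = (
            summaries.loc[rest, "bai_mean"]
            + summaries.loc[rest, "phq9_mean"]
            + (summaries.loc[rest, "pclc_mean"] - 17.0)
        )
        minimal = elevation.idxmin()
        names[minimal] = "minimal_symptom"
        rest.remove(minimal)
    if len(rest) == 2:
        by_bai = summaries.loc[rest, "bai_mean"].sort_values(ascending=False)
        names[by_bai.index[0]] = "anxiety"
        names[by_bai.index[1]] = "mixed_anxiety_depression"
    return names


class PhenotypeCluster:
    """Density-based phenotype model over the three instrument totals.

    Parameters
    ----------
    scores
        DataFrame containing ``bai_total``, ``phq9_total``,
        ``pclc_total`` (extra columns are carried through to
        ``assignments()``).
    embedding
        :class:`EmbeddingConfig`; ``seed`` here overrides its seed.
    min_cluster_size, min_samples
        HDBSCAN density parameters; defaults ``max(10, ceil(0.04 * n))``
        and 30 — the high ``min_samples`` trades coverage for purity by
        pushing ambiguous boundary points into the noise group.
    reassign_noise
        If True, noise points are attached post hoc to the cluster with
        the nearest centroid in embedding space (the reading in which
        outliers are folded back into the partition).
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        embedding: EmbeddingConfig | None = None,
        min_cluster_size: int | None = None,
        min_samples: int | None = None,
        selection_method: str = "leaf",
        reassign_noise: bool = False,
        seed: int | None = None,
    ):
        missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
        if missing:
            raise ValueError(f"scores frame lacks columns {missing}")
        self.data = scores.reset_index(drop=True)
        self.embedding_config = embedding or EmbeddingConfig()
        if seed is not None:
            self.embedding_config.seed = int(seed)
        n = len(self.data)
        default_mcs = max(10, int(np.ceil(0.04 * n)))
        self.min_cluster_size = min_cluster_size or default_mcs
        self.min_samples = min_samples or 30
        self.selection_method = selection_method
        self.reassign_noise = reassign_noise

    def fit(self) -> "PhenotypeClusterResults":
        X = self.data[list(SCORE_COLUMNS)].to_numpy(dtype=float)
        emb = embed_scores(X, self.embedding_config)
        labels = cluster_embedding(
            emb, self.min_cluster_size, self.min_samples, self.selection_method
        )
        if self.reassign_noise and (labels == NOISE).any():
            real = np.unique(labels[labels != NOISE])
            if real.size:
                centroids = np.stack([emb[labels == c].mean(axis=0) for c in real])
                for i in np.flatnonzero(labels == NOISE):
                    labels[i] = real[
                        np.argmin(np.linalg.norm(centroids - emb[i], axis=1))
                    ]
        return PhenotypeClusterResults(self, emb, labels)


class PhenotypeClusterResults:
    """Fitted phenotype partition with summaries and quality metrics."""

    def __init__(self, model: PhenotypeCluster, embedding: np.ndarray, labels: np.ndarray):
        self.model = model
        self.embedding = embedding
        self.labels = np.asarray(labels)
        data = model.data
        ids = np.unique(self.labels[self.labels != NOISE])
        rows = []
        for cl in ids:
            sub = data.loc[self.labels == cl, list(SCORE_COLUMNS)]
            rows.append(
                {
                    "cluster": int(cl),
                    "n": int(len(sub)),
                    **{
                        f"{c.split('_')[0]}_mean": float(sub[c].mean())
                        for c in SCORE_COLUMNS
                    },
                    **{
                        f"{c.split('_')[0]}_sd": float(sub[c].std(ddof=1))
                        if len(sub) > 1
                        else 0.0
                        for c in SCORE_COLUMNS
                    },
                }
            )
        self.summaries = (
            pd.DataFrame(rows).set_index("cluster")
            if rows
            else pd.DataFrame(columns=["n"])
        )
        self.cluster_sizes = {int(c): int((self.labels == c).sum()) for c in ids}
        self.n_noise = int((self.labels == NOISE).sum())
        try:
            self.silhouette = evaluate_silhouette(embedding, self.labels)
        except ValueError:
            self.silhouette = float("nan")
        self.phenotype_names = (
            label_phenotypes(self.summaries) if len(self.summaries) else {}
        )

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def assignments(self) -> pd.DataFrame:
        """Per-participant table: cluster id, phenotype name, embedding."""
        out = self.model.data.copy()
        out["cluster"] = self.labels
        out["phenotype"] = [
            self.phenotype_names.get(int(lb), "noise" if lb == NOISE else "unlabeled")
            for lb in self.labels
        ]
        for j in range(self.embedding.shape[1]):
            out[f"umap{j + 1}"] = self.embedding[:, j]
        return out

    def ari(self, truth) -> float:
        """Adjusted Rand index against latent labels, noise excluded."""
        return adjusted_rand(np.asarray(truth), self.labels)

    def to_report(self) -> dict:
        return {
            "seed": self.model.embedding_config.seed,
            "min_cluster_size": self.model.min_cluster_size,
            "min_samples": self.model.min_samples,
            "n": int(len(self.model.data)),
            "n_clusters": self.n_clusters,
            "n_noise": self.n_noise,
            "silhouette": None if np.isnan(self.silhouette) else self.silhouette,
            "cluster_sizes": self.cluster_sizes,
            "phenotype_names": {str(k): v for k, v in self.phenotype_names.items()},
            "summaries": self.summaries.reset_index().to_dict(orient="records"),
        }

    def summary(self) -> str:
        buf = io.StringIO()
        print("Phenotype clustering (UMAP + HDBSCAN)", file=buf)
        print(
            f"n = {len(self.model.data)}   clusters = {self.n_clusters}   "
            f"noise = {self.n_noise}   silhouette = {self.silhouette:.3f}",
            file=buf,
        )
        tbl = self.summaries.copy()
        tbl["phenotype"] = [self.phenotype_names[c] for c in tbl.index]
        print(tbl.round(2).to_string(), file=buf)
        return buf.getvalue()
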