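"""Known-truth validation experiments for the whole pipeline.

The study whose conditions the synthetic generator emulates did not
deposit raw data, so the pipeline is validated by property: can it
recover structure that was planted with known ground truth?  Each
experiment here runs the package end to end on seeded synthetic inputs
and returns summary statistics; the acceptance script and the test suite
both call these functions.
"""

from __future__ import annotations

import warnings

import numpy as np

from .benchmarks import null_design, planted_subgroup_design, synergy_design
from .classifier import cv_f1, select_features
from .cohort import CohortConfig, generate_cohort
from .clustering import PhenotypeCluster
from .features import FeatureMatrix, build_interactions
from .instruments import score_dataframe

__all__ = [
    "clustering_recovery",
    "feature_recovery",
    "null_selection",
    "synergy_benefit",
]


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31 - 1))
            for s in np.random.SeedSequence(seed).spawn(n)]


def clustering_recovery(
    n_seeds: int = 20, seed: int = 0, ari_threshold: float = 0.7
) -> dict:
    """Latent-phenotype recovery on default synthetic cohorts (n=277).

    For each seed: generate a cohort, score it, run the clustering model,
    and compute the ARI between the recovered non-noise labels and the
    latent truth.  Returns the per-seed ARIs and the fraction at or above
    ``ari_threshold``.
    """
    seeds = _spawn(seed, 2 * n_seeds)
    aris, n_clusters, silhouettes = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_seeds):
            cohort = generate_cohort(CohortConfig(seed=seeds[k]))
            scored = score_dataframe(cohort)
            res = PhenotypeCluster(scored, seed=seeds[n_seeds + k]).fit()
            aris.append(res.ari(scored["latent_phenotype"]))
            n_clusters.append(res.n_clusters)
            silhouettes.append(res.silhouette)
    aris = np.asarray(aris)
    return {
        "aris": aris.tolist(),
        "n_clusters": n_clusters,
        "silhouettes": silhouettes,
        "median_ari": float(np.median(aris)),
        "recovery_rate": float(np.mean(aris >= ari_threshold)),
        "n_seeds": n_seeds,
    }


def feature_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    n: int = 300,
    n_noise: int = 50,
    min_hits: int = 2,
) -> dict:
    """Forward-selection recovery of planted informative features.

    Each seed builds a fresh design with 3 complementary informative
    features among ``n_noise`` noise features and runs the saturation-rule
    selection; a seed counts as recovered when at least ``min_hits`` of
    the 3 are selected.
    """
    seeds = _spawn(seed, n_seeds)
    hits, f1s, n_selected = [], [], []
    for s in seeds:
        X, y, informative = planted_subgroup_design(n=n, n_noise=n_noise, seed=s)
        trace, selected = select_features(FeatureMatrix(X), y, seed=s)
        hits.append(len(set(selected) & set(informative)))
        n_selected.append(len(selected))
        kept = [st for st in trace.steps if st.decision == "kept"]
        f1s.append(kept[-1].mean_f1)
    hits = np.asarray(hits)
    return {
        "hits": hits.tolist(),
        "n_selected": n_selected,
        "final_f1": f1s,
        "recovery_rate": float(np.mean(hits >= min_hits)),
        "n_seeds": n_seeds,
    }


def null_selection(n_seeds: int = 20, seed: int = 0, n: int = 300) -> dict:
    """Selection behavior when no feature carries signal.

    A correct saturation rule stops at (or just past) the one-feature
    base model with chance-level cross-validated F1.
    """
    seeds = _spawn(seed, n_seeds)
    n_selected, f1s = [], []
    for s in seeds:
        X, y = null_design(n=n, seed=s)
        trace, selected = select_features(FeatureMatrix(X), y, seed=s)
        n_selected.append(len(selected))
        kept = [st for st in trace.steps if st.decision == "kept"]
        f1s.append(kept[-1].mean_f1)
    return {
        "n_selected": n_selected,
        "final_f1": f1s,
        "mean_f1": float(np.mean(f1s)),
        "stop_rate": float(np.mean(np.asarray(n_selected) <= 2)),
        "n_seeds": n_seeds,
    }


def synergy_benefit(n_seeds: int = 20, seed: int = 0, n: int = 300) -> dict:
    """Interaction features on a planted synergy: F1 with product/quotient
    columns vs the base-features-only model, same folds and seeds."""
    seeds = _spawn(seed, n_seeds)
    without, with_, sd_without = [], [], []
    for s in seeds:
        X, y, _ = synergy_design(n=n, seed=s)
        m0, s0, _ = cv_f1(X.to_numpy(), y, seed=s)
        fm = build_interactions(FeatureMatrix(X), "two_way")
        m1, _, _ = cv_f1(fm.data.to_numpy(), y, seed=s)
        without.append(m0)
        with_.append(m1)
        sd_without.append(s0)
    without = np.asarray(without)
    with_ = np.asarray(with_)
    sd_without = np.asarray(sd_without)
    return {
        "f1_without": without.tolist(),
        "f1_with": with_.tolist(),
        "mean_without": float(without.mean()),
        "mean_with": float(with_.mean()),
        "within_1sd_rate": float(np.mean(with_ >= without - sd_without)),
        "n_seeds": n_seeds,
    }
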