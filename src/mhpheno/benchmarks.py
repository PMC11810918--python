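"""Known-truth benchmark designs for the classification engine.

Three synthetic designs with analytically known structure, used to check
that feature selection finds real signal, stops on noise, and that
interaction features help when (and only when) a synergy exists:

* planted-subgroup design — each informative feature marks a different
  subgroup of the positive class (shifted by ``effect`` SDs), so every
  informative feature adds complementary discriminative coverage and a
  correct forward selection keeps accumulating them, while noise
  features add nothing;
* pure-noise design — no feature carries signal; selection should stop
  immediately at chance-level F1;
* synergy design — class risk is high exactly when two features move in
  the same direction (their product is positive), a relationship a
  product interaction feature linearizes.

These are deliberately idealized: continuous independent Gaussian
features, balanced classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "planted_subgroup_design",
    "null_design",
    "synergy_design",
]


def _noise_frame(rng: np.random.Generator, n: int, k: int, prefix: str) -> pd.DataFrame:
    return pd.DataFrame(
        rng.standard_normal((n, k)),
        columns=[f"{prefix}{i:02d}" for i in range(k)],
    )


def planted_subgroup_design(
    n: int = 300,
    n_noise: int = 50,
    effect: float = 3.0,
    proportions: tuple[float, ...] = (0.60, 0.25, 0.15),
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Balanced binary design with complementary informative features.

    Positives are split into subgroups of the given ``proportions``; the
    j-th informative feature is shifted by ``effect`` SDs only within
    subgroup j.  The graded subgroup sizes make the dominant feature
    clearly the best single predictor (it covers most positives), while
    each further informative feature covers positives the previous ones
    miss — so a correct forward selection keeps adding them, with gains
    far above what any of the ``n_noise`` pure-noise features offers.
    Returns (features, labels, names of the informative features).
    """
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    X = _noise_frame(rng, n, n_noise, "noise")
    informative = []
    sizes = np.rint(np.asarray(proportions) / np.sum(proportions) * n_pos).astype(int)
    sizes[-1] = n_pos - sizes[:-1].sum()
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    for j in range(len(proportions)):
        name = f"signal{j}"
        col = rng.standard_normal(n)
        col[bounds[j] : bounds[j + 1]] += effect
        X.insert(j, name, col)
        informative.append(name)
    perm = rng.permutation(n)
    return X.iloc[perm].reset_index(drop=True), y[perm], informative


def null_design(
    n: int = 300, n_features: int = 53, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Balanced labels independent of every feature."""
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    rng.shuffle(y)
    return _noise_frame(rng, n, n_features, "noise"), y


def synergy_design(
    n: int = 300,
    n_noise: int = 8,
    p_high: float = 0.85,
    p_low: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, tuple[str, str]]:
    """Two features whose *joint* sign determines risk (no marginal effect).

    P(y=1) is ``p_high`` when x1*x2 > 0 and ``p_low`` otherwise, so each
    feature alone is uninformative but their product is a near-perfect
    predictor.  Returns (features, labels, the synergy pair).
    """
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    p = np.where(x1 * x2 > 0, p_high, p_low)
    y = (rng.random(n) < p).astype(int)
    X = _noise_frame(rng, n, n_noise, "noise")
    X.insert(0, "syn1", x1)
    X.insert(1, "syn2", x2)
    return X, y, ("syn1", "syn2")
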