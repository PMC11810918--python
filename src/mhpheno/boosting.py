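"""Gradient-boosted tree backend behind a minimal model-config contract.

The classification engine needs nothing beyond "fit a boosted tree
ensemble with logistic loss, return raw scores"; class probabilities are
always the sigmoid 1/(1+exp(-raw)) and the decision boundary is 0.5.
Two interchangeable backends satisfy the contract:

* ``"lightgbm"`` (default) — LightGBM through its native train API,
  single-threaded and deterministic, with a per-fit overhead small
  enough for greedy forward selection (thousands of small fits).
* ``"sklearn"`` — scikit-learn's GradientBoostingClassifier.

Defaults (200-ish row training folds, handful of features): 30 rounds,
depth 3 / 7 leaves, learning rate 0.1, minimum 10 samples per leaf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoostConfig", "GradientBooster", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic link: raw additive score -> probability (0 maps to 0.5)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class BoostConfig:
    backend: str = "lightgbm"
    n_estimators: int = 30
    max_depth: int = 3
    num_leaves: int = 7
    learning_rate: float = 0.1
    min_samples_leaf: int = 10

    def validate(self) -> None:
        if self.backend not in ("lightgbm", "sklearn"):
            raise ValueError(f"unknown booster backend {self.backend!r}")
        if self.n_estimators < 1 or self.learning_rate <= 0:
            raise ValueError("need n_estimators >= 1 and learning_rate > 0")


class GradientBooster:
    """Binary boosted-tree classifier with logistic loss.

    `fit` expects y in {0, 1}; `predict_raw` returns the additive score
    (log-odds), `predict_proba` its sigmoid.
    """

    def __init__(self, config: BoostConfig | None = None, seed: int = 0):
        self.config = config or BoostConfig()
        self.config.validate()
        self.seed = int(seed) % (2**31 - 1)
        self._model = None

    def fit(self, X, y) -> "GradientBooster":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        cfg = self.config
        if cfg.backend == "lightgbm":
            import lightgbm as lgb

            params = {
                "objective": "binary",
                "num_leaves": cfg.num_leaves,
                "max_depth": cfg.max_depth,
                "learning_rate": cfg.learning_rate,
                "min_data_in_leaf": cfg.min_samples_leaf,
                "max_bin": 15,
                "force_col_wise": True,
                "verbose": -1,
                "num_threads": 1,
                "deterministic": True,
                "seed": self.seed,
            }
            dset = lgb.Dataset(X, label=y, params=params)
            self._model = lgb.train(
                params, dset, num_boost_round=cfg.n_estimators,
                keep_training_booster=True,
            )
        else:
            from sklearn.ensemble import GradientBoostingClassifier

            self._model = GradientBoostingClassifier(
                n_estimators=cfg.n_estimators,
                max_depth=cfg.max_depth,
                learning_rate=cfg.learning_rate,
                min_samples_leaf=cfg.min_samples_leaf,
                random_state=self.seed,
            ).fit(X, y.astype(int))
        return self

    def predict_raw(self, X) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("booster not fitted")
        X = np.asarray(X, dtype=float)
        if self.config.backend == "lightgbm":
            return np.asarray(self._model.predict(X, raw_score=True))
        return np.asarray(self._model.decision_function(X))

    def predict_proba(self, X) -> np.ndarray:
        return sigmoid(self.predict_raw(X))

    def predict(self, X) -> np.ndarray:
        """Class labels at the 0.5 probability boundary."""
        return (self.predict_proba(X) > 0.5).astype(int)
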