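"""Boosted classification of one phenotype against another.

The canonical contrast is the PTSD phenotype vs the minimal-symptom
phenotype.  The engine:

1. prunes redundant features (|r| > 0.65 groups keep their highest-MIC
   member, MIC taken against the class label),
2. optionally appends two-way product/quotient interaction features,
3. greedily forward-selects features by mean F1 over stratified 5-fold
   cross-validation repeated 5 times (25 trials), stopping at model
   saturation — when the best candidate's gain no longer exceeds one SD
   of the current model's trial-level F1 — or at a feature cap,
4. reports mean/SD F1, the full selection trace, partial-dependence
   grids and pairwise interaction heatmaps from a final model fit on all
   rows.

F1 is the harmonic mean of precision and recall on the designated
positive class, computed per held-out fold from the confusion counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

from .boosting import BoostConfig, GradientBooster
from .features import FeatureMatrix, build_interactions, dedupe_features, encode_features

__all__ = [
    "f1_score",
    "cv_f1",
    "select_features",
    "SelectionStep",
    "SelectionTrace",
    "partial_dependence",
    "interaction_heatmap",
    "PhenotypeClassifier",
    "PhenotypeClassifierResults",
    "DEFAULT_CLASSIFIER_FEATURES",
    "CATEGORICAL_LEVELS",
]


def f1_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Harmonic mean of precision and recall for the positive (1) class.

    0 when the model finds no true positive (zero precision or recall).
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def cv_f1(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    boost: BoostConfig | None = None,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> tuple[float, float, list[float]]:
    """Mean, SD and per-trial F1 over repeated stratified cross-validation.

    Each of the folds x repeats held-out folds yields one F1 value; the
    SD is the sample SD over those trials.  Folds are stratified so both
    classes appear in every training fold.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError("minority class smaller than the fold count")
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=int(seed) % (2**31 - 1)
    )
    trial_f1 = []
    for i, (tr, te) in enumerate(splitter.split(X, y)):
        model = GradientBooster(boost, seed=seed + i).fit(X[tr], y[tr])
        trial_f1.append(f1_score(y[te], model.predict(X[te])))
    mean = float(np.mean(trial_f1))
    sd = float(np.std(trial_f1, ddof=1))
    return mean, sd, trial_f1


@dataclass
class SelectionStep:
    step: int
    candidate: str
    mean_f1: float
    sd_f1: float
    decision: str  # kept | stopped


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return [s.candidate for s in self.steps if s.decision == "kept"]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])


def select_features(
    features: FeatureMatrix | pd.DataFrame,
    y: np.ndarray,
    boost: BoostConfig | None = None,
    max_features: int = 10,
    saturation_sd: float = 1.0,
    saturation_baseline: str = "current",
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> tuple[SelectionTrace, list[str]]:
    """Greedy forward selection under the 1-SD saturation rule.

    At each step every remaining candidate is scored by the repeated-CV
    mean F1 of the current set plus that candidate; the best joins the
    model only if its gain exceeds ``saturation_sd`` times the SD of the
    reference model's 25 trial F1 values.  The reference is the current
    model (default) or the first one-feature model
    (``saturation_baseline="first"``).  Ties break lexicographically.
    The trace records every decision, ending with a stop or pool
    exhaustion.
    """
    data = features.data if isinstance(features, FeatureMatrix) else features
    names = list(data.columns)
    if not names:
        raise ValueError("empty feature pool")
    if saturation_baseline not in ("current", "first"):
        raise ValueError(f"unknown saturation baseline {saturation_baseline!r}")
    trace = SelectionTrace()
    selected: list[str] = []
    current_mean, current_sd = -np.inf, 0.0
    first_sd = None
    pool = list(names)
    step = 0
    while pool and len(selected) < max_features:
        step += 1
        scores = {}
        for cand in pool:
            m, s, _ = cv_f1(
                data[selected + [cand]].to_numpy(),
                y,
                boost,
                folds=folds,
                repeats=repeats,
                seed=seed,
            )
            scores[cand] = (m, s)
        best = min(scores, key=lambda c: (-scores[c][0], c))
        best_mean, best_sd = scores[best]
        if not selected:
            selected.append(best)
            pool.remove(best)
            current_mean, current_sd = best_mean, best_sd
            first_sd = best_sd
            trace.steps.append(SelectionStep(step, best, best_mean, best_sd, "kept"))
            continue
        ref_sd = current_sd if saturation_baseline == "current" else first_sd
        gain = best_mean - current_mean
        if gain > saturation_sd * ref_sd:
            selected.append(best)
            pool.remove(best)
            current_mean, current_sd = best_mean, best_sd
            trace.steps.append(SelectionStep(step, best, best_mean, best_sd, "kept"))
        else:
            trace.steps.append(SelectionStep(step, best, best_mean, best_sd, "stopped"))
            break
    return trace, selected


def partial_dependence(
    model: GradientBooster,
    data: pd.DataFrame,
    feature: str,
    grid: Sequence[float] | None = None,
    grid_size: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean predicted probability as the feature sweeps a grid.

    For each grid value g, the feature column is set to g for every row
    and predictions are averaged — the standard marginal partial
    dependence.  Default grid: the feature's unique values if few, else
    equally spaced quantiles.
    """
    if feature not in data.columns:
        raise KeyError(f"unknown feature {feature!r}")
    if grid is None:
        uniq = np.unique(data[feature].to_numpy(float))
        if len(uniq) <= grid_size:
            grid = uniq
        else:
            grid = np.quantile(
                data[feature].to_numpy(float), np.linspace(0, 1, grid_size)
            )
    grid = np.asarray(grid, dtype=float)
    base = data.to_numpy(float)
    j = data.columns.get_loc(feature)
    means = np.empty(len(grid))
    for i, g in enumerate(grid):
        mod = base.copy()
        mod[:, j] = g
        means[i] = float(model.predict_proba(mod).mean())
    return grid, means


def interaction_heatmap(
    model: GradientBooster,
    data: pd.DataFrame,
    pair: tuple[str, str],
    grids: tuple[Sequence[float], Sequence[float]] | None = None,
    grid_size: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D partial dependence: mean probability over a grid x grid sweep."""
    fa, fb = pair
    for f in pair:
        if f not in data.columns:
            raise KeyError(f"unknown feature {f!r}")
    if grids is None:
        grids = tuple(
            np.unique(data[f].to_numpy(float))
            if data[f].nunique() <= grid_size
            else np.quantile(data[f].to_numpy(float), np.linspace(0, 1, grid_size))
            for f in pair
        )
    ga, gb = (np.asarray(g, dtype=float) for g in grids)
    base = data.to_numpy(float)
    ja, jb = data.columns.get_loc(fa), data.columns.get_loc(fb)
    out = np.empty((len(ga), len(gb)))
    for i, va in enumerate(ga):
        mod = base.copy()
        mod[:, ja] = va
        for k, vb in enumerate(gb):
            mod[:, jb] = vb
            out[i, k] = float(model.predict_proba(mod).mean())
    return ga, gb, out


#: Cohort columns offered to the classifier by default: demographics,
#: HIV indices, medical history, medications, function, cognition, and
#: item-level adversity / positive-affect responses.  The instrument
#: totals that defined the phenotypes are deliberately excluded.
DEFAULT_CLASSIFIER_FEATURES = (
    ["age", "sex", "education_years", "married"]
    + ["on_art", "art_duration_months", "art_adherence_pct", "viral_load_detectable"]
    + [
        "diabetes",
        "hypertension",
        "sensory_symptoms",
        "balance_difficulty",
        "fit_seizure",
        "smoke",
    ]
    + ["med_niazid", "med_dapsone", "med_flagyl", "med_antihypertensive"]
    + ["karnofsky"]
    + [
        "avlt_total",
        "avlt_delayed",
        "avlt_recognition",
        "pegs_dominant",
        "pegs_nondominant",
        "color_trails1_time",
        "color_trails2_time",
        "ct1_near_misses",
        "ct2_near_misses",
        "symbol_digit",
        "timed_gait",
    ]
    + [f"ctq_pa_item{k}" for k in range(1, 6)]
    + [f"ctq_sa_item{k}" for k in range(1, 6)]
    + [f"cesd_pa_item{k}" for k in range(1, 5)]
)

CATEGORICAL_LEVELS = {"sex": ("female", "male")}


class PhenotypeClassifier:
    """Boosted-tree contrast between two phenotypes.

    Parameters
    ----------
    data
        Cohort table with a phenotype assignment column.
    positive, negative
        Phenotype labels forming the contrast; the F1 positive class is
        ``positive``.
    feature_columns, categorical
        Cohort columns to use and the ordinal encoding of any
        non-numeric ones.
    interactions
        ``"none"`` or ``"two_way"``.
    interaction_pool_size
        If set, interactions are built only among the this-many
        top-MIC base features (keeps the candidate pool tractable).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        positive: str,
        negative: str,
        phenotype_col: str = "phenotype",
        feature_columns: Sequence[str] = DEFAULT_CLASSIFIER_FEATURES,
        categorical=None,
        interactions: str = "none",
        interaction_pool_size: int | None = None,
        boost: BoostConfig | None = None,
        r_threshold: float = 0.65,
        max_features: int = 10,
        saturation_sd: float = 1.0,
        saturation_baseline: str = "current",
        folds: int = 5,
        repeats: int = 5,
        seed: int = 0,
    ):
        sub = data[data[phenotype_col].isin([positive, negative])].reset_index(drop=True)
        if sub.empty or (sub[phenotype_col] == positive).sum() == 0:
            raise ValueError("positive class absent from the data")
        self.y = (sub[phenotype_col] == positive).to_numpy().astype(int)
        self.positive, self.negative = positive, negative
        self.base = encode_features(
            sub,
            list(feature_columns),
            categorical if categorical is not None else CATEGORICAL_LEVELS,
        )
        self.interactions = interactions
        self.interaction_pool_size = interaction_pool_size
        self.boost = boost or BoostConfig()
        self.r_threshold = r_threshold
        self.max_features = max_features
        self.saturation_sd = saturation_sd
        self.saturation_baseline = saturation_baseline
        self.folds = folds
        self.repeats = repeats
        self.seed = int(seed)

    def _candidate_matrix(self) -> FeatureMatrix:
        fm = dedupe_features(self.base, self.y, self.r_threshold)
        if self.interactions == "two_way":
            pool = fm
            if (
                self.interaction_pool_size is not None
                and len(fm.names) > self.interaction_pool_size
            ):
                from .mic import mic

                ranked = sorted(
                    fm.names,
                    key=lambda n: (-mic(fm.data[n].to_numpy(), self.y.astype(float)), n),
                )
                pool = fm.select(ranked[: self.interaction_pool_size])
            fm = build_interactions(pool, "two_way", self.r_threshold)
            fm = dedupe_features(fm, self.y, self.r_threshold)
        return fm

    def fit(self) -> "PhenotypeClassifierResults":
        fm = self._candidate_matrix()
        trace, selected = select_features(
            fm,
            self.y,
            self.boost,
            max_features=self.max_features,
            saturation_sd=self.saturation_sd,
            saturation_baseline=self.saturation_baseline,
            folds=self.folds,
            repeats=self.repeats,
            seed=self.seed,
        )
        final = fm.select(selected)
        mean, sd, trials = cv_f1(
            final.data.to_numpy(),
            self.y,
            self.boost,
            folds=self.folds,
            repeats=self.repeats,
            seed=self.seed,
        )
        model = GradientBooster(self.boost, seed=self.seed).fit(
            final.data.to_numpy(), self.y
        )
        return PhenotypeClassifierResults(self, fm, trace, final, model, mean, sd, trials)


class PhenotypeClassifierResults:
    """Selected features, CV performance and model-inspection products."""

    def __init__(self, spec, candidates, trace, features, model, mean_f1, sd_f1, trials):
        self.model_spec = spec
        self.candidates = candidates
        self.trace = trace
        self.features = features
        self.model = model
        self.mean_f1 = mean_f1
        self.sd_f1 = sd_f1
        self.trial_f1 = trials

    @property
    def selected(self) -> list[str]:
        return self.features.names

    def partial_dependence(self, feature: str, grid=None):
        return partial_dependence(self.model, self.features.data, feature, grid)

    def interaction_heatmap(self, pair, grids=None):
        return interaction_heatmap(self.model, self.features.data, pair, grids)

    def pdp_table(self) -> pd.DataFrame:
        rows = []
        for name in self.selected:
            grid, means = self.partial_dependence(name)
            for g, m in zip(grid, means):
                rows.append({"feature": name, "value": g, "mean_probability": m})
        return pd.DataFrame(rows)

    def heatmap_table(self) -> pd.DataFrame:
        rows = []
        for name in self.selected:
            prov = self.features.provenance.get(name, ("base",))
            if prov[0] in ("product", "quotient"):
                pa, pb = prov[1], prov[2]
                if pa in self.selected and pb in self.selected:
                    ga, gb, mat = self.interaction_heatmap((pa, pb))
                    for i, va in enumerate(ga):
                        for k, vb in enumerate(gb):
                            rows.append(
                                {
                                    "interaction": name,
                                    pa: va,
                                    pb: vb,
                                    "mean_probability": mat[i, k],
                                }
                            )
        return pd.DataFrame(rows)

    def to_report(self) -> dict:
        return {
            "positive": self.model_spec.positive,
            "negative": self.model_spec.negative,
            "interactions": self.model_spec.interactions,
            "seed": self.model_spec.seed,
            "n": int(len(self.model_spec.y)),
            "n_positive": int(self.model_spec.y.sum()),
            "n_candidates": len(self.candidates.names),
            "selected_features": self.selected,
            "provenance": {n: list(self.features.provenance[n]) for n in self.selected},
            "mean_f1": self.mean_f1,
            "sd_f1": self.sd_f1,
            "trial_f1": self.trial_f1,
            "selection_trace": [vars(s) for s in self.trace.steps],
        }

    def summary(self) -> str:
        buf = io.StringIO()
        print(
            f"Boosted classification: {self.model_spec.positive} vs "
            f"{self.model_spec.negative} "
            f"(interactions: {self.model_spec.interactions})",
            file=buf,
        )
        print(
            f"F1 = {self.mean_f1:.3f} (SD {self.sd_f1:.3f}) over "
            f"{len(self.trial_f1)} CV trials; "
            f"{len(self.selected)} features from "
            f"{len(self.candidates.names)} candidates",
            file=buf,
        )
        print(self.trace.as_frame().round(3).to_string(index=False), file=buf)
        return buf.getvalue()
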