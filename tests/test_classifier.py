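"""Boosted classification: F1, repeated CV, saturation-rule selection,
partial dependence and interaction heatmaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import f1_score as sklearn_f1

from mhpheno.benchmarks import null_design, planted_subgroup_design, synergy_design
from mhpheno.boosting import BoostConfig, GradientBooster, sigmoid
from mhpheno.classifier import (
    PhenotypeClassifier,
    cv_f1,
    f1_score,
    interaction_heatmap,
    partial_dependence,
    select_features,
)
from mhpheno.features import FeatureMatrix


class TestF1:
    def test_harmonic_mean_arithmetic(self):
        # precision 0.5, recall 1 -> F1 = 2/3
        y_true = np.array([1, 1, 0, 0])
        y_pred = np.array([1, 1, 1, 1])
        assert f1_score(y_true, y_pred) == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0])
        assert f1_score(y, y) == 1.0

    def test_no_true_positive_is_zero(self):
        assert f1_score(np.array([1, 1, 0]), np.array([0, 0, 1])) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.integers(2, 60), st.integers(0, 2**31 - 1))
    def test_matches_confusion_matrix_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, n)
        y_pred = rng.integers(0, 2, n)
        assert f1_score(y_true, y_pred) == pytest.approx(
            sklearn_f1(y_true, y_pred, zero_division=0)
        )


def test_sigmoid_zero_is_decision_boundary():
    assert sigmoid(0.0) == 0.5
    assert sigmoid(np.array([-50, 50])) == pytest.approx([0, 1], abs=1e-6)


class TestBooster:
    def test_raw_score_sigmoid_is_probability(self, rng):
        X = rng.normal(size=(100, 3))
        y = (X[:, 0] > 0).astype(int)
        m = GradientBooster(seed=1).fit(X, y)
        p = m.predict_proba(X)
        assert np.allclose(p, sigmoid(m.predict_raw(X)))
        assert ((p > 0.5) == (m.predict(X) == 1)).all()

    def test_backends_agree_on_separable_data(self, rng):
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(int)
        for backend in ("lightgbm", "sklearn"):
            m = GradientBooster(BoostConfig(backend=backend), seed=1).fit(X, y)
            assert f1_score(y, m.predict(X)) > 0.95

    def test_nonbinary_labels_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        with pytest.raises(ValueError, match="binary"):
            GradientBooster().fit(X, np.arange(30))


class TestCvF1:
    def test_returns_25_trials(self, rng):
        X = rng.normal(size=(120, 3))
        y = (X[:, 0] + rng.normal(0, 0.5, 120) > 0).astype(int)
        mean, sd, trials = cv_f1(X, y, seed=3)
        assert len(trials) == 25
        assert mean == pytest.approx(np.mean(trials))
        assert sd == pytest.approx(np.std(trials, ddof=1))

    def test_perfectly_separable_gives_f1_one(self, rng):
        X = np.linspace(-2, 2, 100)[:, None]
        y = (X[:, 0] > 0).astype(int)
        mean, sd, _ = cv_f1(X, y, seed=0)
        assert mean == 1.0 and sd == 0.0

    def test_reproducible_under_seed(self, rng):
        X = rng.normal(size=(100, 4))
        y = rng.integers(0, 2, 100)
        assert cv_f1(X, y, seed=9) == cv_f1(X, y, seed=9)

    def test_tiny_minority_class_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        y = np.zeros(50, dtype=int)
        y[:3] = 1
        with pytest.raises(ValueError, match="minority"):
            cv_f1(X, y, seed=0)


class TestSelection:
    def test_single_perfect_feature_stops_after_one(self, rng):
        X = pd.DataFrame(
            {"perfect": np.linspace(-1, 1, 200), "junk": rng.normal(size=200)}
        )
        y = (X["perfect"] > 0).astype(int).to_numpy()
        trace, sel = select_features(FeatureMatrix(X), y, seed=0)
        assert sel == ["perfect"]
        assert trace.steps[0].mean_f1 == pytest.approx(1.0)

    def test_planted_subgroups_recovered(self):
        X, y, informative = planted_subgroup_design(n=300, n_noise=20, seed=4)
        trace, sel = select_features(FeatureMatrix(X), y, seed=4)
        assert len(set(sel) & set(informative)) >= 2
        assert trace.steps[0].candidate == "signal0"

    def test_null_features_stop_at_chance(self):
        X, y = null_design(n=300, n_features=20, seed=6)
        trace, sel = select_features(FeatureMatrix(X), y, seed=6)
        assert len(sel) <= 2
        assert trace.steps[0].mean_f1 < 0.7

    def test_trace_is_bitwise_reproducible(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        y = (X["a"] + rng.normal(0, 1, 100) > 0).astype(int).to_numpy()
        t1, s1 = select_features(FeatureMatrix(X), y, seed=5)
        t2, s2 = select_features(FeatureMatrix(X), y, seed=5)
        assert s1 == s2
        assert [vars(a) for a in t1.steps] == [vars(b) for b in t2.steps]

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError, match="empty"):
            select_features(pd.DataFrame(), np.array([0, 1]), seed=0)


class TestPartialDependence:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {"risk": rng.uniform(-2, 2, 300), "ignored": rng.normal(size=300)}
        )
        y = (rng.random(300) < sigmoid(2 * X["risk"].to_numpy())).astype(int)
        model = GradientBooster(seed=0).fit(X.to_numpy(), y)
        return model, X

    def test_monotone_risk_feature_gives_monotone_pdp(self, fitted):
        model, X = fitted
        grid, means = partial_dependence(model, X, "risk", grid_size=8)
        assert means[-1] > means[0] + 0.3
        # allow small local non-monotonicity from tree steps
        assert np.all(np.diff(means) > -0.08)

    def test_ignored_feature_gives_flat_pdp(self, fitted):
        model, X = fitted
        _, means = partial_dependence(model, X, "ignored", grid_size=8)
        assert means.max() - means.min() < 0.1

    def test_probabilities_in_unit_interval(self, fitted):
        model, X = fitted
        _, means = partial_dependence(model, X, "risk")
        assert ((0 <= means) & (means <= 1)).all()

    def test_unknown_feature_raises(self, fitted):
        model, X = fitted
        with pytest.raises(KeyError):
            partial_dependence(model, X, "nope")


class TestInteractionHeatmap:
    def test_synergy_maximal_in_joint_high_corner(self):
        X, y, (f1, f2) = synergy_design(n=400, seed=2)
        model = GradientBooster(seed=2).fit(X.to_numpy(), y)
        ga, gb, mat = interaction_heatmap(model, X, (f1, f2), grid_size=5)
        # same-sign corners carry the risk in this design
        same = (mat[0, 0] + mat[-1, -1]) / 2
        opposite = (mat[0, -1] + mat[-1, 0]) / 2
        assert same > opposite + 0.2

    def test_constant_model_gives_constant_matrix(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        y = np.zeros(100, dtype=int)
        y[:50] = 1

        class Flat:
            def predict_proba(self, Z):
                return np.full(len(Z), 0.5)

        _, _, mat = interaction_heatmap(Flat(), X, ("a", "b"), grid_size=4)
        assert np.allclose(mat, 0.5)


class TestInteractionBenefit:
    def test_planted_synergy_with_interactions_not_worse(self):
        """Across seeds, mean F1 with product/quotient features stays
        within one SD of (and typically above) the base-feature model."""
        from mhpheno.features import build_interactions

        wins = 0
        for seed in range(5):
            X, y, _ = synergy_design(n=300, seed=seed)
            base = FeatureMatrix(X)
            m0, s0, _ = cv_f1(X.to_numpy(), y, seed=seed)
            m1, _, _ = cv_f1(
                build_interactions(base, "two_way").data.to_numpy(), y, seed=seed
            )
            assert m1 >= m0 - s0
            wins += m1 > m0
        assert wins >= 3


class TestPhenotypeClassifierModel:
    @pytest.fixture(scope="class")
    def assigned(self):
        from mhpheno.cohort import CohortConfig, generate_cohort
        from mhpheno.instruments import score_dataframe

        scored = score_dataframe(generate_cohort(CohortConfig(seed=11)))
        name = {"C1": "ptsd", "C2": "anxiety", "C3": "mixed_anxiety_depression",
                "C4": "minimal_symptom"}
        return scored.assign(phenotype=scored["latent_phenotype"].map(name))

    def test_contrast_fits_and_reports(self, assigned):
        res = PhenotypeClassifier(
            assigned, positive="ptsd", negative="minimal_symptom", seed=3,
        ).fit()
        report = res.to_report()
        assert 0 <= report["mean_f1"] <= 1
        assert len(report["trial_f1"]) == 25
        assert report["selected_features"] == res.selected
        assert len(res.selected) <= 10
        # sensory symptoms (50% vs 5% planted rates) should carry signal
        assert res.mean_f1 > 0.6
        text = res.summary()
        assert "ptsd" in text and "F1" in text

    def test_latent_truth_never_among_candidates(self, assigned):
        res = PhenotypeClassifier(
            assigned, positive="ptsd", negative="minimal_symptom", seed=3,
        ).fit()
        assert "latent_phenotype" not in res.candidates.names
        assert all("pclc" not in n and "bai_item" not in n for n in res.candidates.names)

    def test_missing_positive_class_raises(self, assigned):
        with pytest.raises(ValueError, match="positive class"):
            PhenotypeClassifier(assigned, positive="nope", negative="minimal_symptom")
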