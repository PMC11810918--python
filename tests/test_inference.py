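"""Referent-cluster comparisons: Welch t, Pearson chi-square."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mhpheno.inference import (
    chi_square,
    compare_to_referent,
    format_p,
    t_test,
    t_test_from_samples,
)


class TestTTest:
    def test_equal_groups_give_t0_p1(self):
        r = t_test(5, 2, 30, 5, 2, 30)
        assert r.statistic == 0 and r.p == 1

    def test_group_swap_negates_t_keeps_p(self):
        a = t_test(6, 2, 30, 5, 3, 40)
        b = t_test(5, 3, 40, 6, 2, 30)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_published_age_contrast_is_highly_significant(self):
        """Anxiety-phenotype age 49.59 (8.08, n=32) vs minimal-symptom
        41.74 (6.86, n=39): Welch p < 0.001."""
        r = t_test(49.59, 8.08, 32, 41.74, 6.86, 39)
        assert r.p < 0.001
        # independent oracle: scipy's summary-statistics Welch test
        oracle = stats.ttest_ind_from_stats(
            49.59, 8.08, 32, 41.74, 6.86, 39, equal_var=False
        )
        assert r.statistic == pytest.approx(oracle.statistic)
        assert r.p == pytest.approx(oracle.pvalue)

    def test_degenerate_variance_conventions(self):
        assert t_test(3, 0, 5, 3, 0, 5).p == 1
        with pytest.warns(UserWarning):
            assert t_test(3, 0, 5, 4, 0, 5).p == 0

    def test_raw_vector_front_end_matches_scipy(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 2, 35)
        r = t_test_from_samples(x, y)
        oracle = stats.ttest_ind(x, y, equal_var=False)
        assert r.statistic == pytest.approx(oracle.statistic)
        assert r.p == pytest.approx(oracle.pvalue)

    def test_pooled_variant(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=25)
        r = t_test_from_samples(x, y, variant="pooled")
        oracle = stats.ttest_ind(x, y, equal_var=True)
        assert r.p == pytest.approx(oracle.pvalue)


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        r = chi_square([[10, 20, 30], [20, 40, 60]])
        assert r.statistic == pytest.approx(0)
        assert r.p == pytest.approx(1)

    def test_published_sexual_abuse_contrast(self):
        """PTSD vs minimal-symptom CTQ sexual-abuse categories: the
        headline p = 0.03 (chi2 ~ 6.78, df 2, no correction)."""
        with pytest.warns(UserWarning):  # an expected cell < 5
            r = chi_square([[44, 11, 21], [32, 2, 5]])
        assert r.df == 2
        assert r.statistic == pytest.approx(6.77, abs=0.01)
        assert round(r.p, 2) == 0.03

    def test_published_physical_abuse_contrast(self):
        with pytest.warns(UserWarning):
            r = chi_square([[55, 10, 11], [33, 4, 2]])
        assert r.statistic == pytest.approx(2.68, abs=0.01)
        assert round(r.p, 2) == 0.26

    def test_zero_marginal_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-marginal"):
            r = chi_square([[10, 0, 5], [8, 0, 9]])
        assert r.df == 1

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [0, 0]])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.lists(st.integers(0, 40), min_size=2, max_size=4),
            min_size=2,
            max_size=3,
        ).filter(
            lambda rows: len({len(r) for r in rows}) == 1
            and all(sum(r) > 0 for r in rows)
            and all(sum(col) > 0 for col in zip(*rows))
        )
    )
    def test_matches_brute_force_oracle(self, rows):
        """Pearson statistic equals a hand-rolled sum((O-E)^2/E) with
        df = (r-1)(c-1) and an upper-tail chi2 p."""
        obs = np.array(rows, dtype=float)
        with np.errstate(invalid="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = chi_square(obs)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        stat = ((obs - expected) ** 2 / expected).sum()
        df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
        assert r.statistic == pytest.approx(stat)
        assert r.p == pytest.approx(stats.chi2.sf(stat, df))


def test_format_p_convention():
    assert format_p(0.264) == "0.26"
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.0339) == "0.03"


class TestCompareToReferent:
    @pytest.fixture(scope="class")
    def assigned(self):
        from mhpheno.clustering import PhenotypeCluster
        from mhpheno.cohort import CohortConfig, generate_cohort
        from mhpheno.instruments import score_dataframe

        scored = score_dataframe(generate_cohort(CohortConfig(seed=11)))
        # use latent truth as the partition: inference is downstream of any
        # assignment, however obtained
        scored = scored.assign(cluster=scored["latent_phenotype"])
        return scored

    def test_referent_vs_itself_all_p1(self, assigned):
        out = compare_to_referent(assigned, "C4")
        self_rows = out[out["cluster"] == "C4"]
        assert (self_rows["p"] == 1).all()

    def test_default_variable_list(self, assigned):
        out = compare_to_referent(assigned, "C4")
        assert set(out["variable"]) == {
            "age", "sex", "education_years", "viral_load_detectable",
            "ctq_pa_cat", "ctq_sa_cat",
        }
        assert len(out) == 6 * assigned["cluster"].nunique()

    def test_age_contrast_detected(self, assigned):
        """The planted older anxiety phenotype shows up against the referent."""
        out = compare_to_referent(assigned, "C4")
        row = out[(out["cluster"] == "C2") & (out["variable"] == "age")].iloc[0]
        assert row["p"] < 0.01

    def test_unknown_variable_raises(self, assigned):
        with pytest.raises(KeyError, match="nope"):
            compare_to_referent(assigned, "C4", variables=[("nope", "continuous")])

    def test_planted_sa_excess_drives_p_down(self):
        """Monotonicity: stronger planted C1 sexual-abuse excess gives a
        smaller C1-vs-C4 chi-square p."""
        from mhpheno.cohort import CohortConfig, generate_cohort
        from mhpheno.instruments import score_dataframe

        ps = []
        for extreme_prob in (0.15, 0.55):
            cfg = CohortConfig(n=800, seed=31, exact_counts=True)
            cfg.ctq_sa_probs = dict(cfg.ctq_sa_probs)
            cfg.ctq_sa_probs["C1"] = np.array(
                [1 - extreme_prob - 0.1, 0.1, extreme_prob]
            )
            scored = score_dataframe(generate_cohort(cfg))
            scored = scored.assign(cluster=scored["latent_phenotype"])
            out = compare_to_referent(scored, "C4")
            row = out[(out["cluster"] == "C1") & (out["variable"] == "ctq_sa_cat")]
            ps.append(row["p"].iloc[0])
        assert ps[1] < ps[0]

    def test_holm_adjustment_is_monotone(self, assigned):
        out = compare_to_referent(assigned, "C4", adjust="holm")
        mask = out["p_holm"].notna()
        assert (out.loc[mask, "p_holm"] >= out.loc[mask, "p"] - 1e-12).all()
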