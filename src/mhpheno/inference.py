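"""Referent-cluster univariate comparisons.

Each discovered phenotype is compared against a referent cluster (the
minimal-symptom phenotype in the canonical analysis) on a small set of
variables: t-tests for continuous variables, Pearson chi-square for
categorical ones.  Defaults — Welch t, chi-square without continuity
correction, unadjusted p-values — are the conventional choices for this
kind of descriptive cluster comparison; Holm adjustment and a pooled-
variance t are available as options.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import CTQ_CATEGORIES

__all__ = [
    "TestResult",
    "t_test",
    "t_test_from_samples",
    "chi_square",
    "compare_to_referent",
    "format_p",
    "DEFAULT_COMPARISON_VARIABLES",
]


@dataclass
class TestResult:
    """One univariate test with the summaries it was computed from."""

    test: str
    statistic: float
    df: float
    p: float
    summaries: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "p_display": format_p(self.p),
        }


def format_p(p: float, decimals: int = 2, floor: float = 0.001) -> str:
    """Report-table convention: two decimals, '<0.001' below the floor."""
    if np.isnan(p):
        return "NA"
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.{decimals}f}"


def t_test(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "welch",
) -> TestResult:
    """Two-sided two-sample t-test from summary statistics.

    Welch (default) uses the Satterthwaite df; ``variant="pooled"`` is
    the equal-variance test.  Degenerate variances follow the stated
    conventions: both SDs zero with equal means -> p = 1; both zero with
    unequal means -> p = 0 with a warning.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be nonnegative")
    summaries = {"mean1": mean1, "sd1": sd1, "n1": n1, "mean2": mean2, "sd2": sd2, "n2": n2}
    name = f"t_{variant}"
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return TestResult(name, 0.0, float(n1 + n2 - 2), 1.0, summaries)
        warnings.warn("zero variance in both groups with unequal means; p = 0")
        return TestResult(name, np.inf, float(n1 + n2 - 2), 0.0, summaries)
    if variant == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        t = (mean1 - mean2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (
            (v1**2 / (n1 - 1) if v1 else 0.0) + (v2**2 / (n2 - 1) if v2 else 0.0)
        )
    elif variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(name, float(t), float(df), float(p), summaries)


def t_test_from_samples(
    x1: Sequence[float], x2: Sequence[float], variant: str = "welch"
) -> TestResult:
    """Raw-vector front end to :func:`t_test` (NaNs dropped)."""
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    return t_test(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b), variant
    )


def chi_square(
    table: np.ndarray | pd.DataFrame | Sequence[Sequence[float]],
    correction: bool = False,
) -> TestResult:
    """Pearson chi-square test of independence on a contingency table.

    Zero marginal rows/columns are dropped with a warning before testing
    (a category no group endorses carries no information).  No continuity
    correction by default.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError(f"need a table with >=2 rows and columns, got {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if obs.sum() == 0:
        raise ValueError("empty contingency table")
    keep_r = obs.sum(axis=1) > 0
    keep_c = obs.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-marginal rows/columns before chi-square")
        obs = obs[keep_r][:, keep_c]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table degenerate after dropping zero marginals")
    expected = stats.contingency.expected_freq(obs)
    if (expected < 5).any():
        warnings.warn("expected cell count < 5; chi-square approximation is rough")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=correction)
    return TestResult(
        "chi_square", float(stat), float(df), float(p), {"observed": obs.tolist()}
    )


#: (variable, kind) pairs compared against the referent by default:
#: demographics, viral load, and the two adversity categories.
DEFAULT_COMPARISON_VARIABLES = (
    ("age", "continuous"),
    ("sex", "categorical"),
    ("education_years", "continuous"),
    ("viral_load_detectable", "categorical"),
    ("ctq_pa_cat", "categorical"),
    ("ctq_sa_cat", "categorical"),
)


def compare_to_referent(
    df: pd.DataFrame,
    referent,
    variables: Sequence[tuple[str, str]] = DEFAULT_COMPARISON_VARIABLES,
    cluster_col: str = "cluster",
    t_variant: str = "welch",
    correction: bool = False,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Test every non-referent cluster against the referent on each variable.

    Returns a tidy frame (cluster, variable, test, statistic, df, p,
    p_display).  ``adjust="holm"`` appends Holm-adjusted p-values;
    unadjusted values are always retained.
    """
    if referent not in set(df[cluster_col]):
        raise ValueError(f"referent cluster {referent!r} not present")
    ref = df[df[cluster_col] == referent]
    if ref.empty:
        raise ValueError("referent cluster is empty")
    rows = []
    clusters = [c for c in sorted(df[cluster_col].dropna().unique()) ]
    for cl in clusters:
        grp = df[df[cluster_col] == cl]
        for var, kind in variables:
            if var not in df.columns:
                raise KeyError(f"unknown comparison variable {var!r}")
            if kind == "continuous":
                res = t_test_from_samples(grp[var], ref[var], variant=t_variant)
            elif kind == "categorical":
                both = pd.concat([grp[var], ref[var]])
                levels = sorted(both.dropna().unique().tolist())
                if set(levels) <= set(CTQ_CATEGORIES):
                    levels = [c for c in CTQ_CATEGORIES if c in levels]
                tab = np.array(
                    [
                        [(grp[var] == lv).sum() for lv in levels],
                        [(ref[var] == lv).sum() for lv in levels],
                    ],
                    dtype=float,
                )
                if cl == referent:
                    res = TestResult("chi_square", 0.0, float(len(levels) - 1), 1.0)
                elif tab.shape[1] < 2 or min(tab.sum(axis=1)) == 0:
                    res = TestResult("chi_square", np.nan, np.nan, np.nan)
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = chi_square(tab, correction=correction)
            else:
                raise ValueError(f"unknown variable kind {kind!r}")
            rows.append({"cluster": cl, "variable": var, **res.as_row()})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        mask = (out["cluster"] != referent) & out["p"].notna()
        p = out.loc[mask, "p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        out.loc[mask, "p_holm"] = adj
    return out
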