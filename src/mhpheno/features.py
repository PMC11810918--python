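"""Feature matrices for the phenotype classifier.

Handles the three standard preprocessing steps around the booster:

* encoding a cohort table into a numeric :class:`FeatureMatrix` with
  per-column provenance,
* redundancy pruning — within every group of highly correlated features
  (|r| > 0.65, transitive closure) only the member with the highest MIC
  against the class label survives,
* optional two-way interaction construction: for each unordered pair of
  base features a product column (synergy: risk moving in the same
  direction) and a quotient column (divergence: risk moving in opposite
  directions), computed on min-max-scaled inputs with an epsilon-guarded
  denominator so no division can produce an infinity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mic import mic

__all__ = [
    "FeatureMatrix",
    "pairwise_correlation",
    "dedupe_features",
    "build_interactions",
    "encode_features",
]

#: Quotient guard on [0, 1]-scaled denominators.
QUOTIENT_EPS = 1e-6


@dataclass
class FeatureMatrix:
    """Numeric feature table with provenance.

    ``provenance[name]`` is ``("base",)``, ``("product", a, b)`` or
    ``("quotient", numerator, denominator)``.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names {dupes}")
        for c in self.data.columns:
            self.provenance.setdefault(c, ("base",))

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown features {missing}")
        return FeatureMatrix(
            self.data[list(names)].copy(),
            {n: self.provenance[n] for n in names},
        )

    def drop_zero_variance(self) -> "FeatureMatrix":
        keep = [c for c in self.data.columns if self.data[c].nunique(dropna=False) > 1]
        dropped = set(self.data.columns) - set(keep)
        if dropped:
            warnings.warn(f"dropping zero-variance features: {sorted(dropped)}")
        return self.select(keep)


def encode_features(
    df: pd.DataFrame,
    columns: Sequence[str],
    categorical: Mapping[str, Sequence] | None = None,
) -> FeatureMatrix:
    """Build a base FeatureMatrix from cohort columns.

    Numeric columns pass through; columns listed in ``categorical`` are
    ordinal-encoded against the declared level order (binary string
    columns like sex become 0/1).  The encoding is recorded in
    provenance so reports can state it.
    """
    categorical = dict(categorical or {})
    out = {}
    prov = {}
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"unknown cohort column {col!r}")
        s = df[col]
        if col in categorical:
            levels = list(categorical[col])
            codes = s.map({lv: i for i, lv in enumerate(levels)})
            if codes.isna().any() and not s.isna().any():
                bad = sorted(set(s) - set(levels))
                raise ValueError(f"column {col!r} has undeclared levels {bad}")
            out[col] = codes.astype(float)
            prov[col] = ("base", "ordinal:" + ",".join(map(str, levels)))
        else:
            if not pd.api.types.is_numeric_dtype(s):
                raise ValueError(
                    f"column {col!r} is non-numeric; declare its levels as categorical"
                )
            out[col] = s.astype(float)
            prov[col] = ("base",)
    return FeatureMatrix(pd.DataFrame(out, index=df.index), prov)


def pairwise_correlation(features: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix; zero-variance columns raise."""
    data = features.data if isinstance(features, FeatureMatrix) else features
    if data.shape[1] < 2:
        raise ValueError("need at least two features")
    sd = data.std(ddof=0)
    flagged = sd[sd == 0].index.tolist()
    if flagged:
        raise ValueError(f"correlation undefined for zero-variance columns {flagged}")
    return data.corr(method="pearson")


def _correlated_groups(corr: pd.DataFrame, threshold: float) -> list[list[str]]:
    """Connected components of the |r| > threshold graph (union-find)."""
    names = list(corr.columns)
    parent = {n: n for n in names}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in itertools.combinations(names, 2):
        if abs(corr.loc[a, b]) > threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    return list(groups.values())


def dedupe_features(
    features: FeatureMatrix,
    target: Sequence,
    r_threshold: float = 0.65,
) -> FeatureMatrix:
    """Keep, per correlated group, the feature most informative about the target.

    Groups are transitive closures of |r| > ``r_threshold``; within each,
    the member with the highest MIC(feature, target) survives, ties
    broken by lexicographic name.  Surviving features are pairwise within
    threshold except through ties removed with their group.
    """
    y = pd.factorize(np.asarray(target))[0].astype(float)
    if len(y) != len(features):
        raise ValueError("target length does not match feature rows")
    fm = features.drop_zero_variance()
    if len(fm.names) < 2:
        return fm
    corr = pairwise_correlation(fm)
    keep = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for group in _correlated_groups(corr, r_threshold):
            if len(group) == 1:
                keep.append(group[0])
                continue
            scored = sorted(
                ((-mic(fm.data[g].to_numpy(), y), g) for g in group)
            )
            keep.append(scored[0][1])
    keep = [n for n in fm.names if n in set(keep)]  # preserve column order
    return fm.select(keep)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def build_interactions(
    features: FeatureMatrix,
    mode: str = "none",
    r_threshold: float = 0.65,
) -> FeatureMatrix:
    """Append two-way interaction columns (``mode="two_way"``).

    For each unordered pair (A, B): a product ``A*B`` and one quotient
    on min-max-scaled values, ``A/(B+eps)`` with the lexicographically
    first feature as numerator.  A single canonical orientation is kept
    because the two reciprocals carry the same ordering information for
    tree learners, which are invariant to monotone transforms.  Constant
    interaction columns are silently not added.
    """
    if mode == "none":
        return features
    if mode != "two_way":
        raise ValueError(f"unknown interaction mode {mode!r}")
    data = features.data
    cols = {}
    prov = {}
    for a, b in itertools.combinations(features.names, 2):
        xa, xb = data[a].to_numpy(float), data[b].to_numpy(float)
        prod = xa * xb
        if np.ptp(prod) > 0:
            name = f"{a}*{b}"
            cols[name] = prod
            prov[name] = ("product", a, b)
        num, den = (a, b) if a <= b else (b, a)
        sn = _minmax(data[num].to_numpy(float))
        sd = _minmax(data[den].to_numpy(float))
        quot = sn / (sd + QUOTIENT_EPS)
        if np.ptp(quot) > 0:
            name = f"{num}/{den}"
            cols[name] = quot
            prov[name] = ("quotient", num, den)
    if not cols:
        return features
    extra = pd.DataFrame(cols, index=data.index)
    assert np.isfinite(extra.to_numpy()).all(), "interaction produced non-finite values"
    return FeatureMatrix(
        pd.concat([data, extra], axis=1),
        {**features.provenance, **prov},
    )
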