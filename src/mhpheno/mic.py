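"""Maximal information coefficient (MIC) estimation.

MIC measures association between two variables as the maximum, over
two-dimensional grids, of the normalized mutual information of the
gridded data.  The grid search here considers every axis resolution
(kx, ky) with kx * ky <= B(n) = n**alpha (alpha = 0.6 by convention),
places bin edges at equal-frequency quantiles of each margin, and
normalizes the plug-in mutual information by log(min(kx, ky)).  The
result lies in [0, 1]: near 0 for independent variables, approaching 1
for any noiseless functional relationship (linear or not) as n grows.

Equal-frequency (rather than exhaustively optimized) bin placement makes
the estimator fast and deterministic; it can only under-reach the exact
MIC supremum, which is immaterial here because MIC is used to *rank*
features within a correlated group.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["mic"]


def _equal_frequency_bins(x: np.ndarray, k: int) -> np.ndarray | None:
    """Assign each value to one of up to k quantile bins; None if the
    margin collapses to fewer than 2 distinct bins (heavy ties)."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, k + 1)[1:-1]))
    assignment = np.searchsorted(edges, x, side="right")
    if len(np.unique(assignment)) < 2:
        return None
    return assignment


def mic(x, y, alpha: float = 0.6) -> float:
    """MIC of two equal-length numeric vectors (length >= 20).

    A constant input carries no information: returns 0.0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 20:
        raise ValueError(f"MIC needs at least 20 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector passed to mic(); returning 0")
        return 0.0
    b = max(4.0, n**alpha)
    kmax = int(b // 2)
    xbins = {k: _equal_frequency_bins(x, k) for k in range(2, kmax + 1)}
    ybins = {k: _equal_frequency_bins(y, k) for k in range(2, kmax + 1)}
    best = 0.0
    for kx in range(2, kmax + 1):
        ky_max = int(b // kx)
        if ky_max < 2:
            break
        xb = xbins[kx]
        if xb is None:
            continue
        nx = xb.max() + 1
        for ky in range(2, ky_max + 1):
            yb = ybins[ky]
            if yb is None:
                continue
            ny = yb.max() + 1
            joint = np.zeros((nx, ny))
            np.add.at(joint, (xb, yb), 1.0)
            joint /= n
            px = joint.sum(axis=1, keepdims=True)
            py = joint.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = joint * np.log(joint / (px * py))
            mi = float(np.nansum(terms))
            denom = np.log(min(joint.shape[0], joint.shape[1]))
            if denom > 0:
                best = max(best, mi / denom)
    return float(min(best, 1.0))
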