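"""Per-cluster item-level profiles and score-distribution exports.

These are the data products behind the usual figure set: a strip-plot
table of every participant's three totals by cluster, and per-cluster
mean response / endorsement rate for every questionnaire item (the
lollipop-plot data).  Endorsement means responding above the item
minimum — 0 for PHQ-9/BAI items, 1 for PCL-C — so an "endorsed" item is
one with any reported symptom.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import pandas as pd

from .instruments import INSTRUMENTS, Instrument, item_columns

__all__ = ["profile_items", "export_strip_data"]

_TOTAL_COLS = {"bai": "bai_total", "phq9": "phq9_total", "pclc": "pclc_total"}


def profile_items(
    df: pd.DataFrame,
    cluster_col: str = "cluster",
    instruments: Iterable[Instrument | str] = (
        Instrument.PCLC,
        Instrument.PHQ9,
        Instrument.BAI,
    ),
) -> pd.DataFrame:
    """One row per (instrument, item, cluster): mean response + endorsement.

    Clusters with no members are omitted with a warning.  Deterministic:
    plain arithmetic means over the cluster's item responses.
    """
    if cluster_col not in df.columns:
        raise ValueError(f"assignments column {cluster_col!r} missing")
    rows = []
    clusters = sorted(df[cluster_col].dropna().unique())
    for inst in instruments:
        inst = Instrument(inst)
        spec = INSTRUMENTS[inst]
        cols = item_columns(inst)
        if not set(cols) <= set(df.columns):
            warnings.warn(f"no item columns for {inst.value}; skipped")
            continue
        for cl in clusters:
            sub = df.loc[df[cluster_col] == cl, cols]
            if sub.empty:
                warnings.warn(f"cluster {cl!r} empty; rows omitted")
                continue
            for k, col in enumerate(cols, start=1):
                rows.append(
                    {
                        "instrument": inst.value,
                        "item": k,
                        "item_key": col,
                        "cluster": cl,
                        "n": len(sub),
                        "mean_response": float(sub[col].mean()),
                        "endorsement_rate": float(
                            (sub[col] > spec.item_min).mean()
                        ),
                    }
                )
    return pd.DataFrame(rows)


def export_strip_data(df: pd.DataFrame, cluster_col: str = "cluster") -> pd.DataFrame:
    """Long (participant, instrument, total, cluster) table; n x 3 rows.

    Losslessly round-trips the input totals, so re-aggregating it
    reproduces the per-cluster mean/SD summaries.
    """
    missing = [c for c in _TOTAL_COLS.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing total columns {missing}; score the cohort first")
    if cluster_col not in df.columns:
        raise ValueError(f"assignments column {cluster_col!r} missing")
    pid = df["pid"] if "pid" in df.columns else df.index
    out = pd.DataFrame(
        {
            "pid": list(pid) * 3,
            "instrument": [
                i for i in _TOTAL_COLS for _ in range(len(df))
            ],
            "total": pd.concat(
                [df[c] for c in _TOTAL_COLS.values()], ignore_index=True
            ),
            "cluster": list(df[cluster_col]) * 3,
        }
    )
    return out
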