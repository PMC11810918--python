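"""Scoring of the self-report mental-health instruments.

Four questionnaires drive the phenotyping pipeline:

* PHQ-9  — 9 depression items, each rated 0-3, total 0-27.
* BAI    — 21 anxiety items, each rated 0-3, total 0-63.
* PCL-C  — 17 PTSD items, each rated 1-5, total 17-85; a total of 33 or
  more is conventionally read as possible PTSD.
* CTQ physical-abuse (PA) and sexual-abuse (SA) subscales — 5 items each,
  rated 1-5, totals 5-25, collapsed here into three ordered early-life
  adversity categories (none/minimal, low/moderate, moderate/extreme).

Totals are plain item sums.  Severity bands use the published screening
cutoffs; the CTQ categories merge the standard 4-level severity bands
(none / low / moderate / severe) into three by pooling moderate with
severe.  All cutoffs live in module-level constants so alternates can be
tested without touching code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Instrument",
    "InstrumentSpec",
    "INSTRUMENTS",
    "PTSD_THRESHOLD",
    "PHQ9_BANDS",
    "BAI_BANDS",
    "CTQ_CUTOFFS",
    "CTQ_CATEGORIES",
    "score_instrument",
    "band_severity",
    "categorize_ctq",
    "score_dataframe",
    "item_columns",
]


class Instrument(str, Enum):
    """The questionnaires (and CTQ subscales) handled by this module."""

    PHQ9 = "phq9"
    BAI = "bai"
    PCLC = "pclc"
    CTQ_PA = "ctq_pa"
    CTQ_SA = "ctq_sa"


@dataclass(frozen=True)
class InstrumentSpec:
    """Static description of one instrument: item count and response range."""

    name: Instrument
    n_items: int
    item_min: int
    item_max: int

    @property
    def total_min(self) -> int:
        return self.n_items * self.item_min

    @property
    def total_max(self) -> int:
        return self.n_items * self.item_max


INSTRUMENTS: Mapping[Instrument, InstrumentSpec] = {
    Instrument.PHQ9: InstrumentSpec(Instrument.PHQ9, 9, 0, 3),
    Instrument.BAI: InstrumentSpec(Instrument.BAI, 21, 0, 3),
    Instrument.PCLC: InstrumentSpec(Instrument.PCLC, 17, 1, 5),
    Instrument.CTQ_PA: InstrumentSpec(Instrument.CTQ_PA, 5, 1, 5),
    Instrument.CTQ_SA: InstrumentSpec(Instrument.CTQ_SA, 5, 1, 5),
}

#: PCL-C total at or above this flags possible PTSD.
PTSD_THRESHOLD = 33

#: Severity bands as {band name: (lower, upper)} closed integer intervals.
PHQ9_BANDS = {
    "minimal": (0, 4),
    "mild": (5, 9),
    "moderate": (10, 14),
    "moderately_severe": (15, 19),
    "severe": (20, 27),
}
BAI_BANDS = {
    "minimal": (0, 7),
    "mild": (8, 15),
    "moderate": (16, 25),
    "severe": (26, 63),
}

#: CTQ subscale cutoffs: totals <= first value -> none/minimal,
#: <= second -> low/moderate, else moderate/extreme.
CTQ_CUTOFFS = {
    Instrument.CTQ_PA: (7, 9),
    Instrument.CTQ_SA: (5, 7),
}
CTQ_CATEGORIES = ("none_minimal", "low_moderate", "moderate_extreme")

_BANDS = {Instrument.PHQ9: PHQ9_BANDS, Instrument.BAI: BAI_BANDS}


def _as_instrument(instrument: Instrument | str) -> Instrument:
    return Instrument(instrument) if not isinstance(instrument, Instrument) else instrument


def item_columns(instrument: Instrument | str) -> list[str]:
    """Column names ``<instrument>_item<k>`` (1-based) for a wide table."""
    inst = _as_instrument(instrument)
    spec = INSTRUMENTS[inst]
    return [f"{inst.value}_item{k}" for k in range(1, spec.n_items + 1)]


def score_instrument(
    responses: Sequence[float],
    spec: InstrumentSpec | Instrument | str,
    *,
    missing: str = "fail",
) -> float:
    """Sum item responses into an instrument total.

    Parameters
    ----------
    responses
        Ordered item responses; NaN marks a missing item.
    spec
        An :class:`InstrumentSpec` or instrument name.
    missing
        ``"fail"`` (default) returns NaN if any item is missing;
        ``"prorate"`` imputes the mean of the observed items when at most
        one item is missing (rounded to the nearest integer), else NaN.

    Raises
    ------
    ValueError
        Wrong vector length, an out-of-range response (the message names
        the 1-based item index), or an unknown ``missing`` policy.
    """
    if not isinstance(spec, InstrumentSpec):
        spec = INSTRUMENTS[_as_instrument(spec)]
    arr = np.asarray(responses, dtype=float)
    if arr.ndim != 1 or arr.shape[0] != spec.n_items:
        raise ValueError(
            f"{spec.name.value} expects {spec.n_items} items, got shape {arr.shape}"
        )
    miss = np.isnan(arr)
    observed = arr[~miss]
    bad = (observed < spec.item_min) | (observed > spec.item_max)
    if bad.any():
        idx = int(np.flatnonzero(~miss)[np.flatnonzero(bad)[0]])
        raise ValueError(
            f"{spec.name.value} item {idx + 1} response {observed[bad][0]:g} "
            f"outside [{spec.item_min}, {spec.item_max}]"
        )
    n_miss = int(miss.sum())
    if n_miss == 0:
        return float(arr.sum())
    if missing == "fail":
        return float("nan")
    if missing == "prorate":
        if n_miss > 1 or observed.size == 0:
            return float("nan")
        return float(observed.sum() + np.rint(observed.mean()))
    raise ValueError(f"unknown missing policy {missing!r}")


def band_severity(total: float, instrument: Instrument | str) -> str:
    """Map a PHQ-9 or BAI total onto its ordered severity band."""
    inst = _as_instrument(instrument)
    if inst not in _BANDS:
        raise ValueError(f"no severity bands defined for {inst.value}")
    spec = INSTRUMENTS[inst]
    if not (spec.total_min <= total <= spec.total_max) or np.isnan(total):
        raise ValueError(
            f"{inst.value} total {total} outside [{spec.total_min}, {spec.total_max}]"
        )
    for band, (lo, hi) in _BANDS[inst].items():
        if lo <= total <= hi:
            return band
    raise AssertionError("bands do not cover the instrument range")


def categorize_ctq(subscale_total: float, subscale: Instrument | str) -> str:
    """Collapse a CTQ PA/SA subscale total onto the three adversity levels."""
    inst = _as_instrument(subscale)
    if inst not in CTQ_CUTOFFS:
        raise ValueError(f"{inst.value} is not a CTQ subscale")
    spec = INSTRUMENTS[inst]
    if not (spec.total_min <= subscale_total <= spec.total_max) or np.isnan(subscale_total):
        raise ValueError(
            f"{inst.value} total {subscale_total} outside "
            f"[{spec.total_min}, {spec.total_max}]"
        )
    lo, hi = CTQ_CUTOFFS[inst]
    if subscale_total <= lo:
        return CTQ_CATEGORIES[0]
    if subscale_total <= hi:
        return CTQ_CATEGORIES[1]
    return CTQ_CATEGORIES[2]


def score_dataframe(
    df: pd.DataFrame,
    *,
    missing: str = "fail",
    instruments: Iterable[Instrument | str] = (
        Instrument.PHQ9,
        Instrument.BAI,
        Instrument.PCLC,
        Instrument.CTQ_PA,
        Instrument.CTQ_SA,
    ),
) -> pd.DataFrame:
    """Append totals, severity bands, flags and CTQ categories to a wide table.

    Expects item columns named ``<instrument>_item<k>``.  Adds, where the
    instrument is present: ``<instrument>_total``; ``phq9_band`` and
    ``bai_band``; ``ptsd_flag`` (PCL-C total >= 33); ``ctq_pa_cat`` /
    ``ctq_sa_cat``.  The input frame is not mutated.
    """
    out = df.copy()
    for instrument in instruments:
        inst = _as_instrument(instrument)
        cols = item_columns(inst)
        if not set(cols) <= set(df.columns):
            continue
        spec = INSTRUMENTS[inst]
        totals = np.array(
            [score_instrument(row, spec, missing=missing) for row in df[cols].to_numpy()]
        )
        out[f"{inst.value}_total"] = totals
        valid = ~np.isnan(totals)
        if inst in _BANDS:
            bands = np.full(len(totals), None, dtype=object)
            bands[valid] = [band_severity(t, inst) for t in totals[valid]]
            out[f"{inst.value}_band"] = bands
        if inst is Instrument.PCLC:
            if valid.all():
                out["ptsd_flag"] = totals >= PTSD_THRESHOLD
            else:  # NaN-preserving float flag when some totals are missing
                flag = np.full(len(totals), np.nan)
                flag[valid] = (totals[valid] >= PTSD_THRESHOLD).astype(float)
                out["ptsd_flag"] = flag
        if inst in CTQ_CUTOFFS:
            cats = np.full(len(totals), None, dtype=object)
            cats[valid] = [categorize_ctq(t, inst) for t in totals[valid]]
            out[f"{inst.value}_cat"] = cats
    if out.columns.equals(df.columns):
        warnings.warn("no instrument item columns found; nothing scored")
    return out
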