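"""Seeded synthetic cohorts with a latent four-phenotype structure.

The generator draws, for each participant, a latent phenotype (C1-C4),
instrument totals from per-phenotype discretized truncated normals,
item-level responses that sum exactly to those totals (with
phenotype-specific item loadings, e.g. a somatic-heavy BAI profile for
the anxiety phenotype), childhood-trauma categories and item responses,
and the demographic / HIV / medical / cognitive covariates used by the
downstream classifier.  Defaults come from :mod:`mhpheno.calibration`.

Because the targets are means of a *discretized, range-clipped* normal,
drawing from ``N(target, sd)`` directly would bias means that sit near an
instrument floor.  The generator instead solves for the latent normal
mean whose discretized-clipped expectation equals the target exactly.

Ground truth (latent labels, seed, planted effects) travels in
``DataFrame.attrs["ground_truth"]`` and is written as a JSON sidecar by
the pipeline; no analysis stage may consume it except for evaluation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import calibration as cal
from .instruments import INSTRUMENTS, Instrument, InstrumentSpec, item_columns

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "allocate_items",
    "plant_classifier_signal",
    "draw_totals",
    "BAI_SOMATIC_ITEMS",
    "BASELINE_COLUMNS",
]


class ConfigError(ValueError):
    """Raised when a cohort configuration is internally infeasible."""


#: 1-based BAI items conventionally grouped as somatic/physical; the
#: remainder are affective/cognitive.
BAI_SOMATIC_ITEMS = (1, 2, 3, 6, 7, 8, 12, 13, 18, 19, 20, 21)

#: PHQ-9 vegetative items (sleep, fatigue, appetite) and the anhedonia item.
PHQ9_VEGETATIVE_ITEMS = (3, 4, 5)
PHQ9_ANHEDONIA_ITEM = 1
#: PCL-C concentration-difficulty item (under-endorsed by the PTSD phenotype).
PCLC_CONCENTRATION_ITEM = 15


def _default_item_weights() -> dict[str, dict[str, np.ndarray]]:
    """Per-(phenotype, instrument) item loadings planting the published
    item-level signatures: anhedonia-heavy PHQ-9 and affective BAI with
    muted concentration complaints for C1; somatic BAI and vegetative
    PHQ-9 for C2."""
    w: dict[str, dict[str, np.ndarray]] = {}
    for ph in cal.PHENOTYPES:
        phq = np.ones(9)
        bai = np.ones(21)
        pcl = np.ones(17)
        if ph == "C1":
            phq[PHQ9_ANHEDONIA_ITEM - 1] = 2.0
            pcl[PCLC_CONCENTRATION_ITEM - 1] = 0.4
            for k in range(21):
                bai[k] = 1.0 if (k + 1) in BAI_SOMATIC_ITEMS else 1.5
        elif ph == "C2":
            for k in PHQ9_VEGETATIVE_ITEMS:
                phq[k - 1] = 2.0
            for k in range(21):
                bai[k] = 2.5 if (k + 1) in BAI_SOMATIC_ITEMS else 1.0
        w[ph] = {"phq9": phq, "bai": bai, "pclc": pcl}
    return w


#: Columns drawn from a shared baseline distribution (no per-phenotype
#: breakdown is published for them).
BASELINE_COLUMNS = (
    "on_art",
    "art_duration_months",
    "art_adherence_pct",
    "karnofsky",
    "cesd_pa_item1",
    "cesd_pa_item2",
    "cesd_pa_item3",
    "cesd_pa_item4",
)

#: Ranges used when clipping planted shifts on known ordinal columns.
_ORDINAL_RANGES = {
    **{f"cesd_pa_item{k}": (0, 3) for k in range(1, 5)},
    "karnofsky": (50, 100),
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    All distributional fields default to the published per-phenotype
    summaries; ``exact_counts`` swaps the multinomial phenotype draw for
    deterministic largest-remainder counts (useful in regression tests).
    """

    n: int = cal.N_TOTAL
    seed: int = 0
    prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(cal.PREVALENCES)
    )
    score_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: copy.deepcopy(cal.SCORE_MEANS)
    )
    score_sds: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: copy.deepcopy(cal.SCORE_SDS)
    )
    score_windows: Mapping[str, Mapping[str, tuple[int, int]]] = field(
        default_factory=lambda: copy.deepcopy(cal.SCORE_WINDOWS)
    )
    ctq_pa_probs: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: cal.normalized_ctq_probs(cal.CTQ_PA_COUNTS)
    )
    ctq_sa_probs: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: cal.normalized_ctq_probs(cal.CTQ_SA_COUNTS)
    )
    age: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(cal.AGE))
    education: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(cal.EDUCATION_YEARS)
    )
    male_prop: Mapping[str, float] = field(default_factory=lambda: dict(cal.MALE_PROP))
    married_prop: Mapping[str, float] = field(
        default_factory=lambda: dict(cal.MARRIED_PROP)
    )
    undetectable_vl_prop: Mapping[str, float] = field(
        default_factory=lambda: dict(cal.UNDETECTABLE_VL_PROP)
    )
    flag_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: copy.deepcopy(cal.FLAG_RATES)
    )
    cognition: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: copy.deepcopy(cal.COGNITION)
    )
    item_weights: Mapping[str, Mapping[str, np.ndarray]] = field(
        default_factory=_default_item_weights
    )
    exact_counts: bool = False

    def validate(self) -> None:
        p = np.array([self.prevalences[k] for k in cal.PHENOTYPES], dtype=float)
        if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
            raise ConfigError(f"prevalences must be a probability vector, got {p}")
        if self.n < len(cal.PHENOTYPES):
            raise ConfigError(f"n={self.n} smaller than the number of phenotypes")
        for inst_name, means in self.score_means.items():
            spec = INSTRUMENTS[Instrument(inst_name)]
            for ph, m in means.items():
                lo, hi = self.score_windows[inst_name][ph]
                if not (spec.total_min <= lo <= hi <= spec.total_max):
                    raise ConfigError(
                        f"{inst_name}/{ph} window {(lo, hi)} outside "
                        f"[{spec.total_min}, {spec.total_max}]"
                    )
                if not (lo <= m <= hi):
                    raise ConfigError(
                        f"{inst_name} mean {m} for {ph} outside window {(lo, hi)}"
                    )
                if self.score_sds[inst_name][ph] < 0:
                    raise ConfigError(f"negative SD for {inst_name}/{ph}")


# ---------------------------------------------------------------------------
# total-score draws


def _discretized_truncated_pmf(mu: float, sigma: float, lo: int, hi: int) -> np.ndarray:
    """PMF of a N(mu, sigma) discretized to the integers of [lo, hi] and
    renormalized (true truncation to the window).

    Computed in log space so far-tail windows (which arise while moment
    matching pushes mu far outside the window) stay numerically exact.
    """
    from scipy.special import log_ndtr, logsumexp

    v = np.arange(lo, hi + 1)
    za = (v - 0.5 - mu) / sigma
    zb = (v + 0.5 - mu) / sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        # lower-tail form Phi(zb)-Phi(za) is stable for atoms below mu,
        # the survival form Q(za)-Q(zb) for atoms above; pick per atom
        lb_cdf, la_cdf = log_ndtr(zb), log_ndtr(za)
        low = lb_cdf + np.log1p(-np.exp(np.minimum(la_cdf - lb_cdf, -1e-300)))
        la_sf, lb_sf = log_ndtr(-za), log_ndtr(-zb)
        high = la_sf + np.log1p(-np.exp(np.minimum(lb_sf - la_sf, -1e-300)))
        logp = np.where(v < mu, low, high)
    logp[np.isnan(logp)] = -np.inf
    if np.all(np.isinf(logp)):
        p = np.zeros(len(v))
        p[0 if mu < lo else -1] = 1.0
        return p
    return np.exp(logp - logsumexp(logp))


def _match_window_moments(
    target_mean: float, target_sd: float, lo: int, hi: int
) -> np.ndarray:
    """PMF on integers [lo, hi] from a truncated discretized normal whose
    mean equals ``target_mean`` exactly and whose SD is as close to
    ``target_sd`` as the window allows.

    Solved by nested search: for each candidate sigma, the latent mu that
    hits the mean is found by bisection (the truncated mean is monotone
    in mu); sigma is then chosen to minimize the SD mismatch.
    """
    if lo == hi:
        return np.array([1.0])
    if target_sd == 0:
        p = np.zeros(hi - lo + 1)
        p[int(np.rint(target_mean)) - lo] = 1.0
        return p

    def mu_for_mean(sigma: float) -> float:
        # bracket must scale with sigma^2: for sigma >> window width the
        # family degenerates to exponential tilting exp(mu*v/sigma^2)
        span = 12 * sigma + 8 * sigma**2 / max(hi - lo, 1)
        a, b = lo - span, hi + span
        v = np.arange(lo, hi + 1)
        for _ in range(100):
            mid = 0.5 * (a + b)
            m = float((v * _discretized_truncated_pmf(mid, sigma, lo, hi)).sum())
            if m < target_mean:
                a = mid
            else:
                b = mid
        return 0.5 * (a + b)

    v = np.arange(lo, hi + 1)

    def sd_at(sigma: float) -> float:
        p = _discretized_truncated_pmf(mu_for_mean(sigma), sigma, lo, hi)
        m = float((v * p).sum())
        return float(np.sqrt(((v - m) ** 2 * p).sum()))

    # truncated SD is increasing in latent sigma up to the window's cap
    sigmas = np.geomspace(target_sd / 20, max(4 * target_sd, hi - lo), 40)
    best_sigma = min(sigmas, key=lambda s: abs(sd_at(s) - target_sd))
    # local refinement
    for _ in range(3):
        local = np.linspace(best_sigma * 0.7, best_sigma * 1.4, 15)
        best_sigma = min(local, key=lambda s: abs(sd_at(s) - target_sd))
    return _discretized_truncated_pmf(mu_for_mean(best_sigma), best_sigma, lo, hi)


def draw_totals(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    spec: InstrumentSpec,
    window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Integer totals with expectation exactly `mean`, supported on
    ``window`` (default: the full instrument range).

    ``sd == 0`` gives a point mass at ``round(mean)`` — degenerate
    clusters are legitimate study conditions.
    """
    lo, hi = window if window is not None else (spec.total_min, spec.total_max)
    if not (spec.total_min <= lo <= hi <= spec.total_max):
        raise ValueError(f"window {(lo, hi)} outside the instrument range")
    if not (lo <= mean <= hi):
        raise ValueError(f"target mean {mean} outside window {(lo, hi)}")
    if sd == 0 or lo == hi:
        return np.full(n, int(np.rint(mean)), dtype=int)
    key = (round(mean, 6), round(sd, 6), lo, hi)
    pmf = _PMF_CACHE.get(key)
    if pmf is None:
        pmf = _match_window_moments(mean, sd, lo, hi)
        _PMF_CACHE[key] = pmf
    return rng.choice(np.arange(lo, hi + 1), size=n, p=pmf)


_PMF_CACHE: dict[tuple, np.ndarray] = {}


# ---------------------------------------------------------------------------
# item allocation


def allocate_items(
    total: int,
    spec: InstrumentSpec,
    profile_weights: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Split an integer total into item responses summing to it exactly.

    Response "points" above the per-item minimum are distributed
    multinomially with probabilities proportional to ``profile_weights``;
    overflow past the per-item maximum is redistributed among non-full
    items, so expected item loadings track the weights (exactly when no
    item saturates).
    """
    w = np.asarray(profile_weights, dtype=float)
    if w.shape != (spec.n_items,):
        raise ValueError(f"weights length {w.shape} != n_items {spec.n_items}")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    if not (spec.total_min <= total <= spec.total_max):
        raise ValueError(
            f"total {total} unachievable for {spec.name.value} "
            f"[{spec.total_min}, {spec.total_max}]"
        )
    cap = spec.item_max - spec.item_min
    alloc = np.zeros(spec.n_items, dtype=int)
    remaining = int(total - spec.total_min)
    while remaining > 0:
        open_items = alloc < cap
        pw = w * open_items
        if pw.sum() == 0:  # only zero-weight items have room left
            pw = open_items.astype(float)
        add = rng.multinomial(remaining, pw / pw.sum())
        alloc += add
        overflow = np.maximum(alloc - cap, 0)
        alloc -= overflow
        remaining = int(overflow.sum())
    return alloc + spec.item_min


# ---------------------------------------------------------------------------
# CTQ subscale draws

#: Category bands on the 5-25 subscale total, per subscale: (lo, hi) per level.
_CTQ_BANDS = {
    Instrument.CTQ_PA: ((5, 7), (8, 9), (10, 25)),
    Instrument.CTQ_SA: ((5, 5), (6, 7), (8, 25)),
}
#: Within-band geometric decay: abuse totals are strongly right-skewed.
_CTQ_DECAY = 0.55


def _draw_ctq_totals(
    rng: np.random.Generator, cats: np.ndarray, subscale: Instrument
) -> np.ndarray:
    bands = _CTQ_BANDS[subscale]
    out = np.empty(len(cats), dtype=int)
    for level, (lo, hi) in enumerate(bands):
        idx = np.flatnonzero(cats == level)
        if idx.size == 0:
            continue
        support = np.arange(lo, hi + 1)
        w = _CTQ_DECAY ** (support - lo)
        out[idx] = rng.choice(support, size=idx.size, p=w / w.sum())
    return out


# ---------------------------------------------------------------------------
# cohort generation


def _assign_phenotypes(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    p = np.array([config.prevalences[k] for k in cal.PHENOTYPES], dtype=float)
    p = p / p.sum()
    if config.exact_counts:
        base = np.floor(p * config.n).astype(int)
        rem = config.n - base.sum()
        frac = p * config.n - base
        base[np.argsort(-frac)[:rem]] += 1
        labels = np.repeat(np.arange(4), base)
        rng.shuffle(labels)
    else:
        labels = rng.choice(4, size=config.n, p=p)
    return np.array(cal.PHENOTYPES)[labels]


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort as a wide per-participant table.

    Deterministic given ``config.seed``.  Ground truth (seed, latent
    labels, planted effects) is stored in ``attrs["ground_truth"]``; the
    latent phenotype also appears as the ``latent_phenotype`` column,
    which downstream analysis stages must ignore except for evaluation.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    phenotype = _assign_phenotypes(rng, config)
    df = pd.DataFrame({"pid": np.arange(1, n + 1), "latent_phenotype": phenotype})

    # instrument totals and item responses
    for inst_name in ("phq9", "bai", "pclc"):
        inst = Instrument(inst_name)
        spec = INSTRUMENTS[inst]
        totals = np.empty(n, dtype=int)
        for ph in cal.PHENOTYPES:
            idx = np.flatnonzero(phenotype == ph)
            totals[idx] = draw_totals(
                rng,
                idx.size,
                config.score_means[inst_name][ph],
                config.score_sds[inst_name][ph],
                spec,
                window=tuple(config.score_windows[inst_name][ph]),
            )
        items = np.empty((n, spec.n_items), dtype=int)
        for i in range(n):
            w = config.item_weights[phenotype[i]][inst_name]
            items[i] = allocate_items(int(totals[i]), spec, w, rng)
        df[item_columns(inst)] = items

    # CTQ categories -> totals -> items (uniform loadings)
    for inst, probs in (
        (Instrument.CTQ_PA, config.ctq_pa_probs),
        (Instrument.CTQ_SA, config.ctq_sa_probs),
    ):
        spec = INSTRUMENTS[inst]
        cats = np.empty(n, dtype=int)
        for ph in cal.PHENOTYPES:
            idx = np.flatnonzero(phenotype == ph)
            pr = np.asarray(probs[ph], dtype=float)
            cats[idx] = rng.choice(3, size=idx.size, p=pr / pr.sum())
        totals = _draw_ctq_totals(rng, cats, inst)
        items = np.empty((n, spec.n_items), dtype=int)
        uniform = np.ones(spec.n_items)
        for i in range(n):
            items[i] = allocate_items(int(totals[i]), spec, uniform, rng)
        df[item_columns(inst)] = items

    # demographics and HIV indices
    def per_pheno_normal(params, lo, hi, integer=True):
        out = np.empty(n)
        for ph in cal.PHENOTYPES:
            idx = np.flatnonzero(phenotype == ph)
            m, s = params[ph]
            out[idx] = rng.normal(m, s, size=idx.size)
        out = np.clip(out, lo, hi)
        return np.rint(out).astype(int) if integer else np.round(out, 2)

    def per_pheno_flag(rates):
        out = np.empty(n, dtype=int)
        for ph in cal.PHENOTYPES:
            idx = np.flatnonzero(phenotype == ph)
            out[idx] = rng.random(idx.size) < rates[ph]
        return out

    df["age"] = per_pheno_normal(config.age, 18, 80)
    df["education_years"] = per_pheno_normal(config.education, 0, 20)
    df["sex"] = np.where(per_pheno_flag(config.male_prop) == 1, "male", "female")
    df["married"] = per_pheno_flag(config.married_prop)
    df["viral_load_detectable"] = 1 - per_pheno_flag(config.undetectable_vl_prop)

    for flag, rates in config.flag_rates.items():
        df[flag] = per_pheno_flag(rates)

    for col, params in config.cognition.items():
        lo, hi, integer = cal.COGNITION_RANGES[col]
        df[col] = per_pheno_normal(params, lo, hi, integer=integer)

    # shared-baseline covariates (no published per-phenotype breakdown)
    df["on_art"] = (rng.random(n) < 0.97).astype(int)
    df["art_duration_months"] = np.clip(
        np.rint(rng.gamma(4.0, 18.0, size=n)), 1, 300
    ).astype(int)
    df["art_adherence_pct"] = np.round(100 * rng.beta(9.0, 1.0, size=n), 1)
    df["karnofsky"] = rng.choice(
        [70, 80, 90, 100], size=n, p=[0.05, 0.15, 0.40, 0.40]
    )
    for k in range(1, 5):
        df[f"cesd_pa_item{k}"] = rng.choice(4, size=n, p=[0.10, 0.20, 0.30, 0.40])

    df.attrs["ground_truth"] = {
        "seed": int(config.seed),
        "latent_phenotype": phenotype.tolist(),
        "planted_effects": {},
    }
    return df


# ---------------------------------------------------------------------------
# planted classifier signal


def plant_classifier_signal(
    cohort: pd.DataFrame, effects: Mapping[str, Mapping] | None
) -> pd.DataFrame:
    """Overwrite named features with known phenotype associations.

    ``effects`` maps a column name to either
    ``{"kind": "rate", "by_phenotype": {phenotype: P(flag=1)}}`` for a
    binary flag (members of unlisted phenotypes keep their values) or
    ``{"kind": "shift", "by_phenotype": {phenotype: delta}}`` for an
    additive shift on a numeric column (clipped to the column's known
    ordinal range where one is declared).  The effect list is recorded in
    ``attrs["ground_truth"]["planted_effects"]`` for recovery tests.
    An empty/None spec is a no-op (the null case).
    """
    out = cohort.copy()
    out.attrs = copy.deepcopy(cohort.attrs)
    if not effects:
        return out
    truth = out.attrs.setdefault("ground_truth", {"planted_effects": {}})
    phenotype = np.asarray(cohort["latent_phenotype"])
    # independent stream so planting does not perturb the base cohort draw
    rng = np.random.default_rng(int(truth.get("seed", 0)) + 987_654_321)
    for name, spec in effects.items():
        if name not in out.columns:
            raise KeyError(f"unknown feature {name!r}")
        kind = spec.get("kind")
        by = spec.get("by_phenotype", {})
        if kind == "rate":
            col = out[name].to_numpy().astype(int)
            for ph, rate in by.items():
                idx = np.flatnonzero(phenotype == ph)
                col[idx] = (rng.random(idx.size) < float(rate)).astype(int)
            out[name] = col
        elif kind == "shift":
            col = out[name].to_numpy().astype(float)
            for ph, delta in by.items():
                idx = np.flatnonzero(phenotype == ph)
                col[idx] = col[idx] + float(delta)
            if name in _ORDINAL_RANGES:
                lo, hi = _ORDINAL_RANGES[name]
                col = np.clip(np.rint(col), lo, hi)
            out[name] = col
        else:
            raise ValueError(f"effect kind must be 'rate' or 'shift', got {kind!r}")
        truth.setdefault("planted_effects", {})[name] = dict(spec)
    return out
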