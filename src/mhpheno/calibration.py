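"""Default calibration of the synthetic cohort generator.

The generator emulates a cohort of 277 virally suppressed adults with HIV
in which four latent mental-health phenotypes coexist:

* C1 — PTSD phenotype (n=76, 27%): mean PCL-C above the clinical
  threshold, elevated but sub-threshold BAI and PHQ-9.
* C2 — anxiety phenotype (n=32, 12%): modest BAI elevation with a
  somatic-heavy item profile; oldest group.
* C3 — mixed anxiety/depression phenotype (n=130, 47%): mild depressive
  symptoms, low anxiety.
* C4 — minimal-symptom phenotype (n=39, 14%): essentially no endorsed
  symptoms (BAI identically zero).

Per-phenotype score means/SDs, childhood-trauma category frequencies,
demographics and covariate rates below are the published per-cluster
summary statistics of that cohort; they are the fixed study conditions,
not tuning knobs.  Covariates with no published per-cluster breakdown
(Karnofsky, ART duration/adherence, CES-D positive affect) use a shared
baseline distribution defined in :mod:`mhpheno.cohort`.
"""

from __future__ import annotations

import numpy as np

PHENOTYPES = ("C1", "C2", "C3", "C4")
PHENOTYPE_NAMES = {
    "C1": "ptsd",
    "C2": "anxiety",
    "C3": "mixed_anxiety_depression",
    "C4": "minimal_symptom",
}

N_TOTAL = 277
CLUSTER_SIZES = {"C1": 76, "C2": 32, "C3": 130, "C4": 39}
PREVALENCES = {k: v / N_TOTAL for k, v in CLUSTER_SIZES.items()}

#: Per-phenotype (mean, sd) of the instrument totals.
SCORE_MEANS = {
    "bai": {"C1": 7.76, "C2": 5.03, "C3": 1.15, "C4": 0.0},
    "phq9": {"C1": 5.09, "C2": 2.34, "C3": 1.08, "C4": 0.05},
    "pclc": {"C1": 37.14, "C2": 20.81, "C3": 21.52, "C4": 17.1},
}
SCORE_SDS = {
    "bai": {"C1": 7.46, "C2": 1.91, "C3": 1.54, "C4": 0.0},
    "phq9": {"C1": 4.19, "C2": 2.22, "C3": 1.60, "C4": 0.22},
    "pclc": {"C1": 8.80, "C2": 1.67, "C3": 3.1, "C4": 0.31},
}

#: Whole-cohort (mean, sd) of the totals implied by the per-cluster cells.
TOTAL_SAMPLE_MEANS = {"bai": 3.25, "phq9": 2.18, "pclc": 25.10}

#: Per-phenotype score windows (closed integer intervals) on which the
#: total-score distributions live.  Each phenotype occupies a clinically
#: defined region of score space — elevated PCL-C for the PTSD phenotype,
#: upper-minimal/mild BAI for the anxiety phenotype, floor scores for the
#: minimal-symptom phenotype (whose published SDs are exactly those of
#: two-point floor distributions) — reflecting that the phenotypes are
#: density-separated subgroups, not free-ranging overlapping clouds.
#: The windows tile score space disjointly — a data-driven phenotype
#: partition assigns each participant to exactly one region, so the
#: latent classes of a faithful emulation occupy non-overlapping tiles:
#: C1 is the PCL-C-elevated region, C2 the BAI-elevated remainder, C3 the
#: BAI-minimal sub-threshold region, C4 the floor cell.  Within each tile
#: the published mean is matched exactly; a published SD larger than the
#: tile supports is matched as closely as the tile allows.
SCORE_WINDOWS = {
    "bai": {"C1": (0, 63), "C2": (4, 12), "C3": (0, 3), "C4": (0, 0)},
    "phq9": {"C1": (0, 27), "C2": (0, 8), "C3": (0, 6), "C4": (0, 1)},
    "pclc": {"C1": (27, 85), "C2": (17, 26), "C3": (19, 26), "C4": (17, 18)},
}

#: Childhood-trauma category counts (none/minimal, low/moderate,
#: moderate/extreme) per phenotype.
CTQ_PA_COUNTS = {
    "C1": (55, 10, 11),
    "C2": (28, 3, 1),
    "C3": (114, 9, 7),
    "C4": (33, 4, 2),
}
CTQ_SA_COUNTS = {
    "C1": (44, 11, 21),
    "C2": (27, 5, 0),
    "C3": (105, 15, 10),
    "C4": (32, 2, 5),
}

AGE = {"C1": (42.92, 9.54), "C2": (49.59, 8.08), "C3": (44.04, 8.49), "C4": (41.74, 6.86)}
EDUCATION_YEARS = {"C1": (6.00, 3.62), "C2": (6.47, 3.94), "C3": (6.03, 3.71), "C4": (6.97, 3.49)}
MALE_PROP = {"C1": 0.37, "C2": 0.41, "C3": 0.50, "C4": 0.54}
MARRIED_PROP = {"C1": 0.49, "C2": 0.41, "C3": 0.68, "C4": 0.59}
UNDETECTABLE_VL_PROP = {"C1": 0.88, "C2": 0.94, "C3": 0.95, "C4": 0.97}

#: Binary flag rates per phenotype (medical history, symptoms, medications).
FLAG_RATES = {
    "diabetes": {"C1": 0.01, "C2": 0.0, "C3": 0.01, "C4": 0.0},
    "hypertension": {"C1": 0.09, "C2": 0.03, "C3": 0.05, "C4": 0.0},
    "sensory_symptoms": {"C1": 0.50, "C2": 0.47, "C3": 0.21, "C4": 0.05},
    "balance_difficulty": {"C1": 0.05, "C2": 0.06, "C3": 0.0, "C4": 0.0},
    "fit_seizure": {"C1": 0.04, "C2": 0.0, "C3": 0.01, "C4": 0.0},
    "smoke": {"C1": 0.13, "C2": 0.16, "C3": 0.07, "C4": 0.08},
    "med_niazid": {"C1": 0.63, "C2": 0.75, "C3": 0.70, "C4": 0.82},
    "med_dapsone": {"C1": 0.01, "C2": 0.09, "C3": 0.04, "C4": 0.05},
    "med_flagyl": {"C1": 0.05, "C2": 0.03, "C3": 0.0, "C4": 0.0},
    "med_antihypertensive": {"C1": 0.07, "C2": 0.0, "C3": 0.02, "C4": 0.0},
}

#: Cognitive / motor raw-score (mean, sd) per phenotype.
COGNITION = {
    "avlt_total": {"C1": (49.13, 8.10), "C2": (47.28, 8.10), "C3": (47.42, 8.32), "C4": (47.10, 6.97)},
    "avlt_delayed": {"C1": (10.42, 2.46), "C2": (9.56, 2.71), "C3": (10.02, 2.48), "C4": (9.46, 2.26)},
    "avlt_recognition": {"C1": (14.04, 1.25), "C2": (14.06, 1.13), "C3": (13.63, 1.64), "C4": (12.82, 3.17)},
    "pegs_dominant": {"C1": (83.95, 25.87), "C2": (88.26, 25.12), "C3": (79.60, 21.70), "C4": (77.00, 18.64)},
    "pegs_nondominant": {"C1": (97.84, 31.60), "C2": (105.50, 31.57), "C3": (89.34, 23.77), "C4": (94.32, 27.23)},
    "color_trails1_time": {"C1": (92.59, 36.45), "C2": (99.90, 35.07), "C3": (89.33, 29.67), "C4": (81.57, 27.09)},
    "color_trails2_time": {"C1": (196.33, 72.62), "C2": (197.86, 66.97), "C3": (186.40, 67.08), "C4": (172.19, 62.74)},
    "ct1_near_misses": {"C1": (0.19, 0.40), "C2": (0.06, 0.25), "C3": (0.13, 0.38), "C4": (0.26, 0.72)},
    "ct2_near_misses": {"C1": (0.30, 0.52), "C2": (0.48, 0.89), "C3": (0.30, 0.64), "C4": (0.18, 0.69)},
    "symbol_digit": {"C1": (19.17, 10.60), "C2": (17.69, 9.62), "C3": (18.83, 10.17), "C4": (19.97, 10.59)},
    "timed_gait": {"C1": (11.46, 1.85), "C2": (11.08, 1.28), "C3": (11.19, 1.55), "C4": (10.70, 1.55)},
}

#: Plausible hard ranges for the cognitive scores (clipping bounds for the
#: generator; integer-valued columns are flagged).
COGNITION_RANGES = {
    "avlt_total": (0, 75, True),
    "avlt_delayed": (0, 15, True),
    "avlt_recognition": (0, 15, True),
    "pegs_dominant": (30, 300, False),
    "pegs_nondominant": (30, 300, False),
    "color_trails1_time": (20, 300, False),
    "color_trails2_time": (40, 600, False),
    "ct1_near_misses": (0, 8, True),
    "ct2_near_misses": (0, 8, True),
    "symbol_digit": (0, 110, True),
    "timed_gait": (5, 30, False),
}


def normalized_ctq_probs(counts: dict[str, tuple[int, int, int]]) -> dict[str, np.ndarray]:
    """Category counts -> per-phenotype probability vectors."""
    return {k: np.asarray(v, dtype=float) / sum(v) for k, v in counts.items()}
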