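"""End-to-end pipeline: simulate -> score -> cluster -> profile -> compare -> classify.

Each stage reads the artifacts of its predecessors from an output
directory and writes its own as CSV/JSON, so any stage can be re-run
from persisted inputs.  A run manifest lists every artifact with a
SHA-256 checksum, the seed, and package versions; with a fixed config
and seed two runs produce identical manifests.

All randomness flows from one global seed: stage-specific seeds are
spawned deterministically from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .boosting import BoostConfig
from .classifier import PhenotypeClassifier
from .clustering import NOISE, EmbeddingConfig, PhenotypeCluster
from .cohort import CohortConfig, generate_cohort, plant_classifier_signal
from .inference import compare_to_referent
from .instruments import INSTRUMENTS, Instrument, item_columns, score_dataframe
from .profiles import export_strip_data, profile_items

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "STAGES"]

log = logging.getLogger("mhpheno.pipeline")

STAGES = ("simulate", "score", "cluster", "profile", "compare", "classify")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    outdir: str = "mhpheno_run"
    seed: int = 0
    stages: Sequence[str] = STAGES
    cohort: Mapping = field(default_factory=dict)  # CohortConfig overrides
    planted_effects: Mapping = field(default_factory=dict)
    embedding: Mapping = field(default_factory=dict)  # EmbeddingConfig overrides
    min_cluster_size: int | None = None
    min_samples: int | None = None
    reassign_noise: bool = False
    referent_phenotype: str = "minimal_symptom"
    classifier: Mapping = field(default_factory=dict)
    input_csv: str | None = None  # skip `simulate` and score this file instead

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**payload)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {STAGES}")
        if "simulate" not in self.stages and self.input_csv is None:
            if "score" in self.stages:
                raise ValueError("scoring needs either the simulate stage or input_csv")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def validate_inputs(df: pd.DataFrame, schema: Mapping | None = None) -> pd.DataFrame:
    """Range/type/missingness validation against the instrument schema.

    Returns a tidy violation table (row, column, kind, message); empty
    when the table is clean.  Never mutates the input.  ``schema`` maps
    column names to (min, max) bounds and defaults to every instrument
    item column present.
    """
    if schema is None:
        schema = {}
        for inst in Instrument:
            spec = INSTRUMENTS[inst]
            for col in item_columns(inst):
                schema[col] = (spec.item_min, spec.item_max)
    violations = []
    for col, (lo, hi) in schema.items():
        if col not in df.columns:
            violations.append(
                {"row": -1, "column": col, "kind": "missing_column",
                 "message": f"required column {col!r} absent"}
            )
            continue
        s = pd.to_numeric(df[col], errors="coerce")
        for row in df.index[s.isna() & df[col].notna()]:
            violations.append(
                {"row": int(row), "column": col, "kind": "type",
                 "message": f"non-numeric value {df.loc[row, col]!r}"}
            )
        bad = df.index[(s < lo) | (s > hi)]
        for row in bad:
            violations.append(
                {"row": int(row), "column": col, "kind": "range",
                 "message": f"value {df.loc[row, col]!r} outside [{lo}, {hi}]"}
            )
    return pd.DataFrame(violations, columns=["row", "column", "kind", "message"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        stage: int(s.generate_state(1)[0] % (2**31 - 1))
        for stage, s in zip(STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES)))
    }
    artifacts: dict[str, Path] = {}
    stages_run = []

    cohort = None
    scored = None
    assignments = None
    cluster_report = None

    def need(stage: str) -> bool:
        return stage in config.stages

    if need("simulate"):
        cc = CohortConfig(**{"seed": seeds["simulate"], **dict(config.cohort)})
        cohort = generate_cohort(cc)
        if config.planted_effects:
            cohort = plant_classifier_signal(cohort, config.planted_effects)
        _write_csv(cohort, out / "cohort.csv")
        _write_json(cohort.attrs["ground_truth"], out / "ground_truth.json")
        artifacts["cohort"] = out / "cohort.csv"
        artifacts["ground_truth"] = out / "ground_truth.json"
        stages_run.append("simulate")
        log.info("simulate: n=%d -> %s", len(cohort), out / "cohort.csv")

    if need("score"):
        if cohort is None:
            src = config.input_csv or out / "cohort.csv"
            cohort = pd.read_csv(src)
        bad = validate_inputs(cohort)
        if len(bad):
            _write_csv(bad, out / "validation.csv")
            raise ValueError(
                f"{len(bad)} input violations; see {out / 'validation.csv'}"
            )
        scored = score_dataframe(cohort)
        _write_csv(scored, out / "scored.csv")
        artifacts["scored"] = out / "scored.csv"
        stages_run.append("score")
        log.info("score: wrote totals/bands for %d participants", len(scored))

    if need("cluster"):
        if scored is None:
            scored = pd.read_csv(out / "scored.csv")
        analysis = scored.drop(columns=["latent_phenotype"], errors="ignore")
        model = PhenotypeCluster(
            analysis,
            EmbeddingConfig(**{"seed": seeds["cluster"], **dict(config.embedding)}),
            min_cluster_size=config.min_cluster_size,
            min_samples=config.min_samples,
            reassign_noise=config.reassign_noise,
        )
        res = model.fit()
        assignments = res.assignments()
        cluster_report = res.to_report()
        _write_csv(assignments, out / "assignments.csv")
        _write_json(cluster_report, out / "cluster_summary.json")
        artifacts["assignments"] = out / "assignments.csv"
        artifacts["cluster_summary"] = out / "cluster_summary.json"
        stages_run.append("cluster")
        log.info(
            "cluster: %d clusters, %d noise, silhouette %.3f",
            res.n_clusters, res.n_noise, res.silhouette,
        )

    if need("profile"):
        if assignments is None:
            assignments = pd.read_csv(out / "assignments.csv")
        _write_csv(profile_items(assignments), out / "item_profiles.csv")
        _write_csv(export_strip_data(assignments), out / "strip_data.csv")
        artifacts["item_profiles"] = out / "item_profiles.csv"
        artifacts["strip_data"] = out / "strip_data.csv"
        stages_run.append("profile")

    if need("compare"):
        if assignments is None:
            assignments = pd.read_csv(out / "assignments.csv")
        ref = _referent_cluster(assignments, config.referent_phenotype)
        comparisons = compare_to_referent(assignments, ref)
        _write_csv(comparisons, out / "comparisons.csv")
        artifacts["comparisons"] = out / "comparisons.csv"
        stages_run.append("compare")
        log.info("compare: referent cluster %s", ref)

    if need("classify"):
        if assignments is None:
            assignments = pd.read_csv(out / "assignments.csv")
        reports = {}
        for mode in ("none", "two_way"):
            opts = dict(config.classifier)
            boost = BoostConfig(**opts.pop("boost", {}))
            opts.setdefault("interaction_pool_size", 12)
            res = PhenotypeClassifier(
                assignments,
                positive="ptsd",
                negative="minimal_symptom",
                interactions=mode,
                boost=boost,
                seed=seeds["classify"],
                **opts,
            ).fit()
            reports[mode] = res.to_report()
            _write_csv(res.pdp_table(), out / f"pdp_{mode}.csv")
            heat = res.heatmap_table()
            if len(heat):
                _write_csv(heat, out / f"heatmaps_{mode}.csv")
            log.info(
                "classify[%s]: F1 %.3f (SD %.3f), features %s",
                mode, res.mean_f1, res.sd_f1, res.selected,
            )
        _write_json(reports, out / "classifier_report.json")
        artifacts["classifier_report"] = out / "classifier_report.json"
        stages_run.append("classify")

    manifest = {
        "package": "mhpheno",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages_run": stages_run,
        "artifacts": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in artifacts.items()},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def _referent_cluster(assignments: pd.DataFrame, phenotype: str):
    match = assignments.loc[assignments["phenotype"] == phenotype, "cluster"]
    if match.empty:
        # fall back to the smallest-burden real cluster
        real = assignments[assignments["cluster"] != NOISE]
        if real.empty:
            raise ValueError("no clusters available for comparison")
        burden = real.groupby("cluster")[["bai_total", "phq9_total", "pclc_total"]].mean().sum(axis=1)
        return burden.idxmin()
    return match.iloc[0]
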