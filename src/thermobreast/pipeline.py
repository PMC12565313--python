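"""End-to-end orchestration: simulate (or load) -> extract -> select ->
cross-validate -> evaluate, with on-disk artifacts between stages.

Stages communicate only through files (manifest CSV + grids -> feature
CSV -> selection CSV/JSON -> per-classifier prediction JSON -> report
JSON), so each stage is independently runnable and a run on a synthetic
manifest traverses exactly the same code path as a run on real
radiometric exports.  The report carries a provenance block (config hash,
input hash, seed, package version) and contains no timestamps, so a rerun
with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    CLASSIFIER_KINDS,
    METRIC_NAMES,
    CvRun,
    cross_validate,
    stratified_kfold,
)
from .evaluation import bootstrap_ci, pairwise_compare
from .features import features_table
from .io import BreastSample, load_samples, split_breasts
from .selection import SelectionResult, select_features
from .synthetic import LABEL_CANCER, CohortConfig, LabeledCase, generate_cohort, write_cohort

__all__ = [
    "RunConfig",
    "EvaluationReport",
    "cases_to_samples",
    "study_samples",
    "run_pipeline",
]

log = logging.getLogger("thermobreast")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    Exactly one of ``simulate`` (a :class:`CohortConfig`) or ``manifest``
    (path to an existing cohort manifest CSV) must be given.  ``seed``
    governs every stochastic component: cohort simulation, fold
    shuffling and the bootstrap.
    """

    out_dir: str | Path
    seed: int
    simulate: CohortConfig | None = None
    manifest: str | Path | None = None
    exclude_cancer_contralateral: bool = False
    gray_levels: int = 256
    calibration: tuple[float, float] | None = None
    alpha: float = 0.05
    k: int = 5
    grouping: Literal["sample", "subject"] = "subject"
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    bootstrap_B: int = 2000
    level: float = 0.95

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.manifest is None):
            raise ValueError("give exactly one of simulate= or manifest=")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML/JSON config; a ``simulate:`` mapping becomes a
        :class:`CohortConfig`."""
        raw = yaml.safe_load(Path(path).read_text())
        raw.update(overrides)
        if isinstance(raw.get("simulate"), dict):
            sim = dict(raw["simulate"])
            if "temp_clip" in sim:
                sim["temp_clip"] = tuple(sim["temp_clip"])
            raw["simulate"] = CohortConfig(**sim)
        if raw.get("calibration") is not None:
            raw["calibration"] = tuple(raw["calibration"])
        if "classifiers" in raw:
            raw["classifiers"] = tuple(raw["classifiers"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["manifest"] = None if self.manifest is None else str(self.manifest)
        return d


@dataclass
class EvaluationReport:
    """Everything one run computed, recomputable from config + inputs."""

    selection: SelectionResult
    runs: dict[str, CvRun]
    cv_summary: pd.DataFrame
    bootstrap: pd.DataFrame
    mcnemar: pd.DataFrame
    provenance: dict


def cases_to_samples(
    cases: Sequence[LabeledCase], exclude_cancer_contralateral: bool = False
) -> list[BreastSample]:
    """Split every case into its two per-breast samples.

    ``exclude_cancer_contralateral=True`` drops the unaffected (NA)
    breast of subjects with a unilateral anomaly, the device used to
    reproduce a clinical cohort whose control-breast count reflects
    per-sample exclusions (e.g. the 71 A / 194 NA composition from 97
    control and 42 cancer subjects, 29 of them bilateral).
    """
    samples: list[BreastSample] = []
    for case in cases:
        left, right = split_breasts(
            case.thermogram,
            case.mask,
            subject_id=case.subject_id,
            left_label=case.left_label,
            right_label=case.right_label,
        )
        for s in (left, right):
            if (
                exclude_cancer_contralateral
                and LABEL_CANCER in (case.left_label, case.right_label)
                and s.label != LABEL_CANCER
            ):
                log.info("excluding %s/%s (contralateral of anomalous breast)",
                         s.subject_id, s.side)
                continue
            samples.append(s)
    return samples


def study_samples(config: CohortConfig) -> list[BreastSample]:
    """Generate a cohort and return its study-shaped per-breast samples
    (contralateral breasts of unilateral cancer subjects excluded)."""
    return cases_to_samples(generate_cohort(config), exclude_cancer_contralateral=True)


def _hash_inputs(manifest: Path) -> str:
    h = hashlib.sha256()
    root = manifest.parent
    h.update(manifest.read_bytes())
    df = pd.read_csv(manifest, dtype=str)
    for rec in df.itertuples(index=False):
        h.update((root / rec.file).read_bytes())
        h.update((root / rec.mask_file).read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: RunConfig) -> EvaluationReport:
    """Execute all stages and write the report files under ``out_dir``.

    Classifiers receive only the selected feature columns.  Aborts with a
    stage-named error when a stage cannot proceed (e.g. "selection: no
    features selected").
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage: simulate (optional) ------------------------------------
    if config.simulate is not None:
        cohort_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        manifest = write_cohort(generate_cohort(cohort_cfg), out / "cohort")
        log.info("simulate: wrote %d cases to %s", len(pd.read_csv(manifest)), manifest)
    else:
        manifest = Path(config.manifest)

    # -- stage: extract -------------------------------------------------
    samples = load_samples(manifest)
    if config.exclude_cancer_contralateral:
        drop_subjects = {
            s.subject_id
            for s in samples
            if s.label == LABEL_CANCER
        }
        kept = [
            s
            for s in samples
            if not (s.subject_id in drop_subjects and s.label != LABEL_CANCER)
        ]
        log.info("extract: excluded %d contralateral breasts", len(samples) - len(kept))
        samples = kept
    table = features_table(samples, G=config.gray_levels, calibration=config.calibration)
    features_path = out / "features.csv"
    table.to_csv(features_path, index=False)
    log.info("extract: %d samples -> %s", len(table), features_path)

    # -- stage: select ---------------------------------------------------
    selection = select_features(table, alpha=config.alpha)
    selection.table.to_csv(out / "selection.csv", index=False)
    (out / "selected.json").write_text(json.dumps(selection.selected, indent=2))
    if not selection.selected:
        raise RuntimeError("selection: no features selected at alpha=%g" % config.alpha)
    log.info("select: retained %s", selection.selected)

    # -- stage: cross-validate ------------------------------------------
    plan = stratified_kfold(
        table["label"],
        k=config.k,
        seed=config.seed,
        grouping=config.grouping,
        groups=table["subject_id"] if config.grouping == "subject" else None,
    )
    runs: dict[str, CvRun] = {}
    summary_rows = []
    for kind in config.classifiers:
        run = cross_validate(kind, table[selection.selected], table["label"], plan)
        runs[kind] = run
        run.predictions.to_json(out / f"predictions_{kind.replace('-', '')}.json",
                                orient="records", indent=2)
        for m in METRIC_NAMES:
            summary_rows.append(
                dict(classifier=kind, metric=m,
                     mean=run.mean_metrics[m], sd=run.sd_metrics[m])
            )
    cv_summary = pd.DataFrame(summary_rows)
    cv_summary.to_csv(out / "cv_summary.csv", index=False)

    # -- stage: evaluate -------------------------------------------------
    boot_rows = []
    for i, (kind, run) in enumerate(runs.items()):
        yt = run.predictions["y_true"].to_numpy()
        yp = run.predictions["y_pred"].to_numpy()
        for j, m in enumerate(METRIC_NAMES):
            ci = bootstrap_ci(
                yt, yp, metric=m, B=config.bootstrap_B, level=config.level,
                seed=config.seed + 1000 * i + j,
            )
            boot_rows.append(
                dict(classifier=kind, metric=m, mean=ci.mean,
                     lower=ci.lower, upper=ci.upper, B=ci.B)
            )
    bootstrap = pd.DataFrame(boot_rows)
    bootstrap.to_csv(out / "bootstrap_ci.csv", index=False)
    mcnemar = pairwise_compare(list(runs.values()), level=config.level)
    mcnemar.to_csv(out / "mcnemar.csv", index=False)

    provenance = dict(
        config_hash=_config_hash(config),
        input_hash=_hash_inputs(manifest),
        seed=config.seed,
        version=__version__,
        n_samples=int(len(table)),
        selected_features=selection.selected,
    )
    report = dict(
        provenance=provenance,
        cv_summary=summary_rows,
        bootstrap=boot_rows,
        mcnemar=mcnemar.to_dict(orient="records"),
    )
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return EvaluationReport(
        selection=selection,
        runs=runs,
        cv_summary=cv_summary,
        bootstrap=bootstrap,
        mcnemar=mcnemar,
        provenance=provenance,
    )
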