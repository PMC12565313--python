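"""Synthetic breast-thermogram cohorts.

Generates temperature grids, binary breast masks and per-breast labels
that emulate the structure of a clinical frontal breast-thermogram study:
bilateral smooth temperature fields in roughly the [20, 36] degC display
range, localized hotspots plus vessel-like warm curvilinear structures on
cancer-labeled breasts (the thermal correlates of tumour angiogenesis),
and an imbalanced control/cancer cohort.

The model is deliberately phenomenological, not a bioheat (Pennes)
simulation: a breast is a half-ellipse mask filled with

    baseline + lateral gradient + N(0, noise_sd)

and a cancerous breast additionally receives the pointwise maximum of a
radially decaying Gaussian hotspot (amplitude ``hotspot_delta`` at its
centre) and dilated random-walk "vessel" polylines at amplitude
``hotspot_delta / 2``.  Everything is clipped to ``temp_clip``.

Determinism: a cohort is generated from one global seed, sub-seeded per
subject from ``(seed, subject_index)``, so regenerating any subject in
isolation reproduces its case bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .io import MANIFEST_COLUMNS, Thermogram, write_temperature_grid

__all__ = [
    "CohortConfig",
    "LabeledCase",
    "study_config",
    "breast_masks",
    "generate_breast_field",
    "generate_case",
    "generate_cohort",
    "write_cohort",
]

#: per-breast labels: no anomaly detected / thermal anomaly detected
LABEL_CONTROL = "NA"
LABEL_CANCER = "A"


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the clinical setting being emulated: 99 control and 42
    biopsy-confirmed cancer subjects, a skin-temperature baseline of 28 degC
    with ~1 degC of smooth within-breast lateral variation and 0.2 degC
    pixel noise, 2 degC hotspots on cancerous breasts, and a [20, 36] degC
    display range.  The default grid is 120x160 (desk scale); the full
    640x480-camera geometry is available by configuration.
    """

    n_control_subjects: int = 99
    n_cancer_subjects: int = 42
    grid_height: int = 120
    grid_width: int = 160
    baseline_temp: float = 28.0
    lateral_gradient: float = 1.0
    noise_sd: float = 0.2
    hotspot_delta: float = 2.0
    hotspot_radius: int = 8
    vessel_count: int = 2
    bilateral_cancer_fraction: float = 0.0
    temp_clip: tuple[float, float] = (20.0, 36.0)
    seed: int = 20251013

    def __post_init__(self) -> None:
        if self.n_control_subjects < 0 or self.n_cancer_subjects < 0:
            raise ValueError("subject counts must be >= 0")
        if self.grid_height < 1 or self.grid_width < 1:
            raise ValueError("grid dimensions must be positive")
        if self.hotspot_delta < 0:
            raise ValueError("hotspot_delta must be >= 0")
        if not 0.0 <= self.bilateral_cancer_fraction <= 1.0:
            raise ValueError("bilateral_cancer_fraction must lie in [0, 1]")
        if self.temp_clip[0] >= self.temp_clip[1]:
            raise ValueError("temp_clip.low must be < temp_clip.high")


@dataclass
class LabeledCase:
    """One subject's thermogram, two-breast mask and per-breast labels."""

    thermogram: Thermogram
    mask: np.ndarray
    left_label: str
    right_label: str
    subject_id: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.thermogram.T.shape:
            raise ValueError("mask and thermogram dimensions differ")
        for lab in (self.left_label, self.right_label):
            if lab not in (LABEL_CONTROL, LABEL_CANCER):
                raise ValueError(f"label must be {LABEL_CONTROL!r} or {LABEL_CANCER!r}")


def study_config(**overrides) -> CohortConfig:
    """Cohort configuration shaped like the emulated clinical study.

    97 control subjects contribute 194 control breasts; of 42 cancer
    subjects, 29 carry bilateral findings (``bilateral_cancer_fraction =
    29/42``), giving 71 anomalous breasts.  Dropping the 13 contralateral
    control breasts of the unilateral cancer subjects (see
    ``pipeline.cases_to_samples``) reproduces the 265-sample, 71 A / 194 NA
    composition the downstream validation assumes.
    """
    base = dict(
        n_control_subjects=97,
        n_cancer_subjects=42,
        bilateral_cancer_fraction=29 / 42,
    )
    base.update(overrides)
    return CohortConfig(**base)


def breast_masks(height: int, width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two mirrored half-ellipse breast masks with a gap at the vertical
    midline.

    Returns ``(both, left, right)`` boolean grids; the two components are
    disjoint and symmetric about the image midline, reproducing the
    two-component geometry the left/right splitter assumes.
    """
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    a = 0.30 * height  # row semi-axis
    b = 0.21 * width   # col semi-axis; centres at 0.27/0.73 keep a midline gap
    r0 = 0.50 * height
    left_c, right_c = 0.27 * width, 0.73 * width
    left = ((rows - r0) / a) ** 2 + ((cols - left_c) / b) ** 2 <= 1.0
    right = ((rows - r0) / a) ** 2 + ((cols - right_c) / b) ** 2 <= 1.0
    return left | right, left, right


def _vessel_map(
    breast_mask: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk polylines inside the breast, dilated to 2-px width."""
    path = np.zeros_like(breast_mask, dtype=bool)
    in_rows, in_cols = np.nonzero(breast_mask)
    if in_rows.size == 0 or count <= 0:
        return path
    n_steps = max(breast_mask.shape) // 3
    for _ in range(count):
        i = rng.integers(in_rows.size)
        r, c = float(in_rows[i]), float(in_cols[i])
        theta = rng.uniform(0.0, 2.0 * np.pi)
        for _ in range(n_steps):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < path.shape[0] and 0 <= ci < path.shape[1]):
                break
            if not breast_mask[ri, ci]:
                break
            path[ri, ci] = True
            theta += rng.normal(0.0, 0.4)
            r += np.sin(theta)
            c += np.cos(theta)
    path = ndimage.binary_dilation(path, structure=np.ones((2, 2), dtype=bool))
    return path & breast_mask


def generate_breast_field(
    config: CohortConfig,
    side: Literal["left", "right"],
    cancerous: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Temperature field (full grid) for one breast.

    Base field = ``baseline_temp`` + a low-frequency lateral ramp spanning
    ``lateral_gradient`` degC across the breast (warmer toward the
    sternum) + i.i.d. Gaussian noise.  A cancerous breast adds
    ``max(hotspot, vessels)`` — pointwise maximum, so overlapping anomaly
    structures do not stack above ``hotspot_delta``, and with zero noise
    and zero gradient the in-mask maximum is exactly
    ``baseline_temp + hotspot_delta`` at the hotspot centre.  The field is
    clipped to ``temp_clip``.
    """
    h, w = config.grid_height, config.grid_width
    _, left_m, right_m = breast_masks(h, w)
    breast_mask = left_m if side == "left" else right_m
    cols_present = np.flatnonzero(breast_mask.any(axis=0))
    rows_present = np.flatnonzero(breast_mask.any(axis=1))
    c0, c1 = cols_present[0], cols_present[-1]
    extent = min(rows_present[-1] - rows_present[0], c1 - c0) + 1
    if config.hotspot_delta > 0 and config.hotspot_radius > extent:
        raise ValueError(
            f"hotspot_radius {config.hotspot_radius} exceeds breast extent {extent}"
        )

    cols = np.arange(w, dtype=float)[None, :]
    frac = np.clip((cols - c0) / max(c1 - c0, 1), 0.0, 1.0)
    if side == "right":
        frac = 1.0 - frac  # warmer toward the sternum on both sides
    field = config.baseline_temp + config.lateral_gradient * frac
    field = np.broadcast_to(field, (h, w)).copy()
    field += rng.normal(0.0, config.noise_sd, size=(h, w)) if config.noise_sd > 0 else 0.0

    if cancerous:
        in_rows, in_cols = np.nonzero(breast_mask)
        i = rng.integers(in_rows.size)
        hr, hc = in_rows[i], in_cols[i]
        rr = np.arange(h)[:, None] - hr
        cc = np.arange(w)[None, :] - hc
        sigma = config.hotspot_radius / 2.0
        hotspot = config.hotspot_delta * np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))
        vessels = _vessel_map(breast_mask, config.vessel_count, rng)
        anomaly = np.maximum(hotspot, (config.hotspot_delta / 2.0) * vessels)
        field += anomaly
    return np.clip(field, *config.temp_clip)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, subject_index])


def generate_case(
    config: CohortConfig, subject_index: int, cancerous: bool, bilateral: bool
) -> LabeledCase:
    """Generate one subject's case deterministically from the cohort seed
    and the subject index."""
    rng = _subject_rng(config.seed, subject_index)
    if cancerous:
        if bilateral:
            sides = {"left", "right"}
        else:
            sides = {rng.choice(["left", "right"])}
    else:
        sides = set()
    ambient = max(config.baseline_temp - 4.0, config.temp_clip[0])
    h, w = config.grid_height, config.grid_width
    T = np.full((h, w), ambient, dtype=float)
    both, left_m, right_m = breast_masks(h, w)
    for side, m in (("left", left_m), ("right", right_m)):
        T[m] = generate_breast_field(config, side, side in sides, rng)[m]
    prefix = "canc" if cancerous else "ctrl"
    return LabeledCase(
        thermogram=Thermogram(T),
        mask=both,
        left_label=LABEL_CANCER if "left" in sides else LABEL_CONTROL,
        right_label=LABEL_CANCER if "right" in sides else LABEL_CONTROL,
        subject_id=f"{prefix}{subject_index:04d}",
    )


def generate_cohort(config: CohortConfig) -> list[LabeledCase]:
    """Generate the full cohort: control subjects first, then cancer
    subjects.

    Each cancer subject has one breast labeled ``A``; a fixed number
    ``round(bilateral_cancer_fraction * n_cancer_subjects)`` of them
    (chosen by seeded permutation) have both breasts labeled ``A``, so the
    emitted label counts are exact, not binomially distributed.
    """
    if config.n_control_subjects + config.n_cancer_subjects < 1:
        raise ValueError("cohort must contain at least one subject")
    n_ctrl, n_canc = config.n_control_subjects, config.n_cancer_subjects
    n_bilateral = int(round(config.bilateral_cancer_fraction * n_canc))
    cohort_rng = np.random.default_rng([config.seed, 1 << 20])
    bilateral_idx = set(cohort_rng.permutation(n_canc)[:n_bilateral].tolist())
    cases = [generate_case(config, i, cancerous=False, bilateral=False) for i in range(n_ctrl)]
    cases += [
        generate_case(config, n_ctrl + j, cancerous=True, bilateral=j in bilateral_idx)
        for j in range(n_canc)
    ]
    return cases


def write_cohort(cases: list[LabeledCase], out_dir: str | Path) -> Path:
    """Write a cohort to disk: one ASCII temperature grid and one bilevel
    PNG mask per case, plus ``manifest.csv``.  Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for case in cases:
        grid_name = f"{case.subject_id}.txt"
        mask_name = f"{case.subject_id}_mask.png"
        write_temperature_grid(case.thermogram.T, out_dir / grid_name)
        Image.fromarray(case.mask.astype(np.uint8) * 255, mode="L").save(
            out_dir / mask_name
        )
        records.append(
            dict(
                subject_id=case.subject_id,
                file=grid_name,
                mask_file=mask_name,
                left_label=case.left_label,
                right_label=case.right_label,
            )
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame.from_records(records, columns=MANIFEST_COLUMNS).to_csv(
        manifest, index=False
    )
    return manifest
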