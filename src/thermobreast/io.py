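"""Reading radiometric temperature grids and breast masks, and splitting
the masked breast region into individual left/right breast samples.

Thermograms are stored as plain-text matrices of surface temperatures in
degrees Celsius (one row of the image per line), the dialect in which
radiometric exports of clinical breast thermograms are commonly
distributed.  Masks are bilevel images (PNG) or CSV grids; any value
strictly greater than zero counts as in-mask.

Coordinates are 0-based ``(row, col)`` with row 0 at the top, matching
raster file order.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "Thermogram",
    "BreastSample",
    "ThermogramFormatError",
    "read_temperature_grid",
    "write_temperature_grid",
    "read_mask",
    "split_breasts",
    "read_manifest",
    "load_samples",
]

#: decimals printed by :func:`write_temperature_grid`; 1e-4 degC is far below
#: the ~0.04 degC thermal sensitivity of clinical IR cameras.
GRID_DECIMALS = 4


class ThermogramFormatError(ValueError):
    """A temperature-grid or mask file violates the expected format."""


@dataclass(frozen=True)
class Thermogram:
    """A rectangular grid of surface temperatures in degrees Celsius.

    ``T[x, y]`` is the temperature at row ``x``, column ``y``; ``M`` and
    ``N`` are the row and column counts.
    """

    T: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if T.ndim != 2 or T.shape[0] < 1 or T.shape[1] < 1:
            raise ValueError("temperature grid must be a non-empty 2-D array")
        if not np.all(np.isfinite(T)):
            raise ValueError("temperature grid contains non-finite values")
        object.__setattr__(self, "T", T)

    @property
    def M(self) -> int:
        return self.T.shape[0]

    @property
    def N(self) -> int:
        return self.T.shape[1]


@dataclass
class BreastSample:
    """One breast's in-mask temperature pixels plus its masked crop.

    ``pixels`` is the multiset of in-mask temperatures; ``sub_grid`` and
    ``sub_mask`` are the bounding-box crop of the temperatures and the
    in/out indicator, so ``pixels == sub_grid[sub_mask]``.
    """

    pixels: np.ndarray
    sub_grid: np.ndarray
    sub_mask: np.ndarray
    side: Literal["left", "right"]
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.sub_mask = np.asarray(self.sub_mask, dtype=bool)
        if self.pixels.size < 1:
            raise ValueError("breast sample has no in-mask pixels")
        if self.sub_grid.shape != self.sub_mask.shape:
            raise ValueError("sub_grid and sub_mask shapes differ")


_TOKEN_SPLIT = re.compile(r"[\s;]+")


def read_temperature_grid(path: str | Path) -> Thermogram:
    """Parse a plain-text radiometric grid into a :class:`Thermogram`.

    Accepts whitespace- or semicolon-separated decimal numbers.  Files
    using decimal commas (a dialect seen in radiometric exports) are
    normalized by mapping ``,`` to ``.`` when the file contains no ``.``
    at all; the normalization is logged via a warning.

    Raises
    ------
    ThermogramFormatError
        On an empty file, a ragged row (naming the offending line) or a
        non-numeric token.
    """
    path = Path(path)
    text = path.read_text()
    if "," in text and "." not in text:
        warnings.warn(
            f"{path.name}: decimal commas normalized to points", stacklevel=2
        )
        text = text.replace(",", ".")
    rows: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = [t for t in _TOKEN_SPLIT.split(line.strip()) if t]
        if not tokens:
            continue
        try:
            rows.append([float(t) for t in tokens])
        except ValueError as exc:
            raise ThermogramFormatError(
                f"{path}: non-numeric token on line {lineno}"
            ) from exc
        if len(rows[-1]) != len(rows[0]):
            raise ThermogramFormatError(
                f"{path}: ragged row on line {lineno} "
                f"({len(rows[-1])} values, expected {len(rows[0])})"
            )
    if not rows:
        raise ThermogramFormatError(f"{path}: empty temperature grid")
    return Thermogram(np.asarray(rows, dtype=float))


def write_temperature_grid(T: np.ndarray, path: str | Path) -> None:
    """Write a temperature grid in the plain-text dialect read back by
    :func:`read_temperature_grid` (space-separated, ``.`` decimal)."""
    np.savetxt(path, np.asarray(T, dtype=float), fmt=f"%.{GRID_DECIMALS}f")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a bilevel/grayscale mask image or CSV grid as a boolean array.

    Any value strictly greater than zero is in-mask, so masks stored with
    foreground 1 and foreground 255 behave identically.
    """
    path = Path(path)
    if path.suffix.lower() in {".csv", ".txt"}:
        arr = np.loadtxt(path, delimiter="," if path.suffix.lower() == ".csv" else None)
    else:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("L"))
    return np.asarray(arr) > 0


def _mask_col_bounds(mask: np.ndarray) -> tuple[int, int]:
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size == 0:
        raise ValueError("mask is empty")
    return int(cols[0]), int(cols[-1])


def split_breasts(
    thermogram: Thermogram | np.ndarray,
    mask: np.ndarray,
    *,
    subject_id: str = "",
    left_label: str | None = None,
    right_label: str | None = None,
    division: Literal["mask-bbox", "image-center"] = "mask-bbox",
) -> tuple[BreastSample, BreastSample]:
    """Split the masked breast region at a vertical midline into left and
    right :class:`BreastSample` records.

    The division column is the floor of the horizontal midpoint of the
    mask's bounding box (``division="mask-bbox"``, the default, so the
    split tracks the breast region even when the subject is off-center) or
    of the full image (``division="image-center"``).  Columns strictly left
    of the division column go to the left sample; the division column and
    everything right of it go to the right sample (half-open convention).

    Raises
    ------
    ValueError
        If mask and grid dimensions differ, or one side is empty after the
        split ("unilateral mask", e.g. after a mastectomy).
    """
    T = thermogram.T if isinstance(thermogram, Thermogram) else np.asarray(thermogram, float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != T.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match thermogram shape {T.shape}"
        )
    if division == "mask-bbox":
        c0, c1 = _mask_col_bounds(mask)
        # a mask entirely on one side of the image midline is a single
        # breast (e.g. post-mastectomy); splitting it at its own bbox
        # midpoint would silently halve one breast
        mid = T.shape[1] // 2
        if c1 < mid:
            raise ValueError("unilateral mask: no breast right of the image midline")
        if c0 >= mid:
            raise ValueError("unilateral mask: no breast left of the image midline")
        div = (c0 + c1 + 1) // 2
    elif division == "image-center":
        div = T.shape[1] // 2
    else:
        raise ValueError(f"unknown division mode {division!r}")

    samples = []
    for side, label, m in (
        ("left", left_label, mask & (np.arange(T.shape[1]) < div)[None, :]),
        ("right", right_label, mask & (np.arange(T.shape[1]) >= div)[None, :]),
    ):
        if not m.any():
            raise ValueError(
                f"unilateral mask: no in-mask pixels on the {side} side "
                f"of division column {div}" + (f" (subject {subject_id})" if subject_id else "")
            )
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        crop = np.s_[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
        samples.append(
            BreastSample(
                pixels=T[m],
                sub_grid=T[crop],
                sub_mask=m[crop],
                side=side,
                subject_id=subject_id,
                label=label,
            )
        )
    return samples[0], samples[1]


MANIFEST_COLUMNS = ["subject_id", "file", "mask_file", "left_label", "right_label"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV (columns ``subject_id, file, mask_file,
    left_label, right_label``; paths relative to the manifest)."""
    # keep_default_na: the control label "NA" is data, not a missing value
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ThermogramFormatError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def load_samples(manifest_path: str | Path, **split_kwargs) -> list[BreastSample]:
    """Load every per-breast sample referenced by a manifest CSV."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    out: list[BreastSample] = []
    for rec in read_manifest(manifest_path).itertuples(index=False):
        thermo = read_temperature_grid(root / rec.file)
        mask = read_mask(root / rec.mask_file)
        left, right = split_breasts(
            thermo,
            mask,
            subject_id=rec.subject_id,
            left_label=rec.left_label,
            right_label=rec.right_label,
            **split_kwargs,
        )
        out.extend([left, right])
    return out
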