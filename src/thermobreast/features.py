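"""Per-breast descriptors: nine statistical features computed directly on
the in-mask temperatures plus gray-level co-occurrence (GLCM) texture
features computed on a quantized copy of the masked crop.

The default descriptor set has 13 entries (:data:`FEATURE_NAMES`):

==============  =============================================================
``mean``        average in-mask temperature, degC
``std``         population standard deviation (1/n denominator), degC
``variance``    population variance, degC^2
``skewness``    Pearson-type coefficient ``(mean - median) / std``
``kurtosis``    non-excess kurtosis ``E[(x - mean)^4] / std^4``
``entropy``     Shannon entropy (bits) of the G-level gray histogram
``min, max``    extreme in-mask temperatures, degC
``cv``          coefficient of variation ``std / mean * 100``, percent
``energy``      sum of in-mask temperatures, degC * pixels
``homogeneity`` ``sum P(i,j) / (1 + (i-j)^2)``
``contrast``    ``sum (i-j)^2 P(i,j)``
``correlation`` ``sum (i-mu_x)(j-mu_y) P(i,j) / (sigma_x sigma_y)``
==============  =============================================================

``energy`` is the temperature sum, not the GLCM angular second moment; the
latter is available as an optional 14th feature (``glcm_energy``,
``sum P(i,j)^2``), off by default.

The GLCM accumulates co-occurrences of each pixel with its
distance-1 neighbours in the four directions {0, 45, 90, 135} degrees,
symmetrically (both offset signs), integrated over directions and
normalized to probabilities.  Pairs with either endpoint outside the mask
are skipped, so non-breast pixels never contaminate the texture measures.

Gray levels are produced by an affine quantization of temperature onto
``[0, G-1]`` (default ``G = 256``).  The temperature range mapped onto the
gray axis is a configuration choice: the default is each sample's own
``(min, max)`` (contrast-stretched, scale-free texture), and a fixed
calibration such as ``(20, 36)`` degC can be passed instead for
temperatures-comparable-across-samples texture.  The entropy histogram
reuses the same quantized levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix

from .io import BreastSample

__all__ = [
    "FEATURE_NAMES",
    "GLCM_OFFSETS",
    "FeatureVector",
    "QuantizedSample",
    "Glcm",
    "statistical_features",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "entropy",
    "extract_features",
    "features_table",
]

FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "std",
    "variance",
    "skewness",
    "kurtosis",
    "entropy",
    "min",
    "max",
    "cv",
    "energy",
    "homogeneity",
    "contrast",
    "correlation",
)

#: distance-1 offsets (row, col) for directions {0, 45, 90, 135} degrees;
#: co-occurrence is accumulated symmetrically (each offset and its negation).
GLCM_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass
class FeatureVector:
    """The named per-breast descriptors, in :data:`FEATURE_NAMES` order."""

    mean: float
    std: float
    variance: float
    skewness: float
    kurtosis: float
    entropy: float
    min: float
    max: float
    cv: float
    energy: float
    homogeneity: float
    contrast: float
    correlation: float
    glcm_energy: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {name: getattr(self, name) for name in FEATURE_NAMES}
        if self.glcm_energy is not None:
            out["glcm_energy"] = self.glcm_energy
        return out


@dataclass
class QuantizedSample:
    """Gray-level grid in ``[0, G-1]`` with its in-mask indicator and the
    ``(low, high)`` temperature calibration mapped to the gray axis."""

    levels: np.ndarray
    mask: np.ndarray
    G: int
    calibration: tuple[float, float]


@dataclass
class Glcm:
    """Direction-integrated symmetric co-occurrence probabilities."""

    P: np.ndarray
    G: int
    offsets: tuple[tuple[int, int], ...] = GLCM_OFFSETS

    @property
    def marginal_x(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @property
    def marginal_means(self) -> tuple[float, float]:
        i = np.arange(self.G, dtype=float)
        return float(i @ self.P.sum(axis=1)), float(i @ self.P.sum(axis=0))

    @property
    def marginal_sds(self) -> tuple[float, float]:
        i = np.arange(self.G, dtype=float)
        mx, my = self.marginal_means
        vx = float((i - mx) ** 2 @ self.P.sum(axis=1))
        vy = float((i - my) ** 2 @ self.P.sum(axis=0))
        return math.sqrt(max(vx, 0.0)), math.sqrt(max(vy, 0.0))


def statistical_features(sample: BreastSample) -> dict[str, float]:
    """The nine pixel-statistics descriptors of one breast.

    Moments use the population (1/n) denominator.  Skewness is the
    Pearson-type ``(mean - median) / std`` and kurtosis the non-excess
    ``m4 / std^4``.  For a constant sample both are undefined and reported
    as NaN with an ``undefined-constant`` warning; all other fields are
    still computed.  Temperatures must be positive (Celsius skin
    temperatures always are) so ``cv`` is well defined.
    """
    x = np.asarray(sample.pixels, dtype=float)
    if x.size < 2:
        raise ValueError("statistical features need at least 2 in-mask pixels")
    mu = float(np.mean(x))
    if mu <= 0:
        raise ValueError("mean temperature must be positive for the CV")
    var = float(np.mean((x - mu) ** 2))
    sd = math.sqrt(var)
    if sd == 0.0:
        warnings.warn("undefined-constant: skewness/kurtosis of a constant sample")
        skew = float("nan")
        kurt = float("nan")
    else:
        skew = (mu - float(np.median(x))) / sd
        kurt = float(np.mean((x - mu) ** 4)) / sd**4
    return {
        "mean": mu,
        "std": sd,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "cv": sd / mu * 100.0,
        "energy": float(np.sum(x)),
    }


def quantize(
    sample: BreastSample,
    G: int = 256,
    calibration: tuple[float, float] | None = None,
) -> QuantizedSample:
    """Affine quantization of the masked crop onto gray levels ``[0, G-1]``.

    ``level = floor((clip(T, low, high) - low) / (high - low) * G)`` with
    ``T = high`` mapping to ``G - 1``.  When ``calibration`` is None the
    sample's own in-mask ``(min, max)`` is used; a degenerate constant
    sample maps to all-zero levels with a warning.
    """
    if G < 2:
        raise ValueError("G must be >= 2")
    if calibration is None:
        calibration = (float(np.min(sample.pixels)), float(np.max(sample.pixels)))
        if calibration[0] == calibration[1]:
            warnings.warn("constant sample: all gray levels set to 0")
            levels = np.zeros_like(sample.sub_grid, dtype=np.intp)
            return QuantizedSample(levels, sample.sub_mask, G, calibration)
    low, high = calibration
    if not low < high:
        raise ValueError("calibration low must be < high")
    scaled = (np.clip(sample.sub_grid, low, high) - low) / (high - low) * G
    levels = np.clip(np.floor(scaled).astype(np.intp), 0, G - 1)
    return QuantizedSample(levels, np.asarray(sample.sub_mask, bool), G, calibration)


def _glcm_pairs(q: QuantizedSample) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric co-occurring gray-level pairs ``(i, j)`` over the four
    distance-1 offsets; each unordered pixel pair contributes both
    orientations.  Pairs touching an out-of-mask pixel are excluded."""
    lv, m = q.levels, q.mask
    i_parts: list[np.ndarray] = []
    j_parts: list[np.ndarray] = []
    h, w = lv.shape
    for dr, dc in GLCM_OFFSETS:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        src = np.s_[r0:r1, c0:c1]
        dst = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = m[src] & m[dst]
        a = lv[src][valid]
        b = lv[dst][valid]
        i_parts += [a, b]
        j_parts += [b, a]
    return np.concatenate(i_parts), np.concatenate(j_parts)


def _glcm_features_from_pairs(
    i: np.ndarray, j: np.ndarray, glcm_energy: bool = False
) -> tuple[float, float, float, float | None]:
    """Texture features computed directly on the symmetric pair list.

    Since the co-occurrence probability is uniform over counted pairs,
    every ``sum_{i,j} f(i,j) P(i,j)`` equals the mean of ``f`` over the
    pair list; this avoids materializing the G x G matrix and is exactly
    equivalent to :func:`glcm_features` on :func:`compute_glcm`'s output.
    """
    if i.size == 0:
        raise ValueError("no valid in-mask pixel pairs for the GLCM")
    d2 = (i - j).astype(float) ** 2
    homogeneity = float(np.mean(1.0 / (1.0 + d2)))
    contrast = float(np.mean(d2))
    mx = float(i.mean())
    my = float(j.mean())
    sx = float(np.sqrt(np.mean((i - mx) ** 2)))
    sy = float(np.sqrt(np.mean((j - my) ** 2)))
    if sx * sy == 0.0:
        warnings.warn("constant image: GLCM correlation reported as 1")
        correlation = 1.0
    else:
        correlation = float(np.mean((i - mx) * (j - my)) / (sx * sy))
    asm = None
    if glcm_energy:
        _, counts = np.unique(i.astype(np.int64) * (int(i.max()) + 1) + j, return_counts=True)
        p = counts / i.size
        asm = float(np.sum(p**2))
    return homogeneity, contrast, correlation, asm


def compute_glcm(q: QuantizedSample) -> Glcm:
    """Masked, symmetric, direction-integrated co-occurrence matrix.

    Out-of-mask pixels are recoded to a sentinel level so that any pair
    touching them can be discarded exactly; counts over the four offsets
    and both signs are pooled and normalized to probabilities.
    """
    img = np.where(q.mask, q.levels, q.G).astype(np.uint16 if q.G < 65535 else np.uint32)
    raw = graycomatrix(
        img, distances=[1], angles=list(_GLCM_ANGLES), levels=q.G + 1, symmetric=True
    )
    counts = raw[: q.G, : q.G, 0, :].sum(axis=2).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask pixel pairs for the GLCM")
    return Glcm(P=counts / total, G=q.G)


def glcm_features(g: Glcm) -> tuple[float, float, float]:
    """``(homogeneity, contrast, correlation)`` of a co-occurrence matrix.

    For a constant image both marginal deviations vanish and correlation
    is reported as 1 with a warning (perfect but degenerate co-occurrence).
    """
    i = np.arange(g.G, dtype=float)
    diff2 = (i[:, None] - i[None, :]) ** 2
    homogeneity = float(np.sum(g.P / (1.0 + diff2)))
    contrast = float(np.sum(diff2 * g.P))
    mx, my = g.marginal_means
    sx, sy = g.marginal_sds
    if sx * sy == 0.0:
        warnings.warn("constant image: GLCM correlation reported as 1")
        correlation = 1.0
    else:
        correlation = float(
            np.sum((i[:, None] - mx) * (i[None, :] - my) * g.P) / (sx * sy)
        )
    return homogeneity, contrast, correlation


def entropy(q: QuantizedSample) -> float:
    """Shannon entropy (bits) of the in-mask gray-level histogram, with
    the ``0 * log 0 = 0`` convention; bounded by ``log2(G)``."""
    vals = q.levels[q.mask]
    if vals.size == 0:
        raise ValueError("entropy needs at least one in-mask pixel")
    counts = np.bincount(vals, minlength=q.G)
    p = counts[counts > 0] / vals.size
    return float(-(p * np.log2(p)).sum())


def extract_features(
    sample: BreastSample,
    G: int = 256,
    calibration: tuple[float, float] | None = None,
    include_glcm_energy: bool = False,
) -> FeatureVector:
    """Full descriptor vector for one breast: statistics on raw
    temperatures, plus entropy and GLCM features on the shared quantized
    levels."""
    stats = statistical_features(sample)
    q = quantize(sample, G=G, calibration=calibration)
    homogeneity, contrast, correlation, asm = _glcm_features_from_pairs(
        *_glcm_pairs(q), glcm_energy=include_glcm_energy
    )
    return FeatureVector(
        **stats,
        entropy=entropy(q),
        homogeneity=homogeneity,
        contrast=contrast,
        correlation=correlation,
        glcm_energy=asm,
    )


def features_table(
    samples: Iterable[BreastSample],
    G: int = 256,
    calibration: tuple[float, float] | None = None,
    include_glcm_energy: bool = False,
) -> pd.DataFrame:
    """Feature table: one row per breast with ``subject_id, side, label``
    followed by the named descriptors."""
    rows = []
    for s in samples:
        rec = {"subject_id": s.subject_id, "side": s.side, "label": s.label}
        rec.update(
            extract_features(
                s, G=G, calibration=calibration, include_glcm_energy=include_glcm_energy
            ).as_dict()
        )
        rows.append(rec)
    return pd.DataFrame(rows)
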