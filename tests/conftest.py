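import numpy as np
import pytest

from thermobreast import BreastSample
from thermobreast.features import GLCM_OFFSETS


def make_breast_sample(grid, mask=None, side="left", label=None, subject_id="s0"):
    """BreastSample straight from a grid and optional mask (default full)."""
    grid = np.asarray(grid, dtype=float)
    mask = np.ones_like(grid, dtype=bool) if mask is None else np.asarray(mask, bool)
    return BreastSample(
        pixels=grid[mask], sub_grid=grid, sub_mask=mask,
        side=side, label=label, subject_id=subject_id,
    )


def brute_force_glcm(levels, mask, G):
    """Independent co-occurrence oracle: explicit double loop over every
    pixel and every symmetric distance-1 offset in the four directions."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    counts = np.zeros((G, G), dtype=np.int64)
    h, w = levels.shape
    offsets = list(GLCM_OFFSETS) + [(-dr, -dc) for dr, dc in GLCM_OFFSETS]
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                    counts[levels[r, c], levels[r2, c2]] += 1
    return counts


def brute_force_glcm_features(P):
    """Texture features from a probability matrix by explicit summation."""
    G = P.shape[0]
    hom = con = 0.0
    mx = my = 0.0
    for i in range(G):
        for j in range(G):
            hom += P[i, j] / (1.0 + (i - j) ** 2)
            con += (i - j) ** 2 * P[i, j]
            mx += i * P[i, j]
            my += j * P[i, j]
    vx = vy = cov = 0.0
    for i in range(G):
        for j in range(G):
            vx += (i - mx) ** 2 * P[i, j]
            vy += (j - my) ** 2 * P[i, j]
            cov += (i - mx) * (j - my) * P[i, j]
    sx, sy = np.sqrt(vx), np.sqrt(vy)
    cor = cov / (sx * sy) if sx * sy > 0 else 1.0
    return hom, con, cor


@pytest.fixture
def sample_factory():
    return make_breast_sample


@pytest.fixture
def glcm_oracle():
    return brute_force_glcm


@pytest.fixture
def glcm_feature_oracle():
    return brute_force_glcm_features
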