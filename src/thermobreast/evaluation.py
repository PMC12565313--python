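"""Statistical validation of classifier performance: percentile bootstrap
confidence intervals for the evaluation metrics and exact pairwise
McNemar comparisons.

The bootstrap resamples the pooled out-of-fold ``(y_true, y_pred)`` pairs
with replacement (B = 2000 by default) and recomputes the metric on each
replicate; the reported interval is the (alpha/2, 1 - alpha/2) percentile
of the replicate distribution.  Models are *not* refitted per replicate:
the interval quantifies metric variability given the observed
predictions.

McNemar's test compares two classifiers on identical samples through the
discordant counts b (first correct, second wrong) and c (first wrong,
second correct), using the exact two-sided binomial form

    p = min(1, 2 * P[X <= min(b, c)]),  X ~ Binomial(b + c, 1/2),

which is valid at the small discordant counts typical of a few hundred
samples.  When per-fold predictions are available the per-fold difference
``b - c`` is additionally summarized by its across-fold mean and a
percentile interval over folds; that interval is a descriptive companion,
the exact p-value is the inferential output.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    METRIC_NAMES,
    POSITIVE_LABEL,
    ConfusionCounts,
    CvRun,
)

__all__ = [
    "BootstrapCi",
    "McNemarResult",
    "metric_value",
    "bootstrap_ci",
    "mcnemar_test",
    "pairwise_compare",
]


@dataclass(frozen=True)
class BootstrapCi:
    metric: str
    point: float
    mean: float
    lower: float
    upper: float
    B: int
    level: float
    seed: int
    skipped: int = 0


@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    p_value: float
    difference: float | None = None  # mean per-fold (b - c)
    ci: tuple[float, float] | None = None
    no_discordance: bool = False


def metric_value(
    y_true: np.ndarray, y_pred: np.ndarray, metric: str, positive=POSITIVE_LABEL
) -> float:
    """Raw metric value from prediction pairs; NaN when undefined (zero
    denominator), so bootstrap replicates can be skipped cleanly."""
    c = ConfusionCounts.from_predictions(y_true, y_pred, positive)
    num_den = {
        "accuracy": (c.TP + c.TN, c.total),
        "precision": (c.TP, c.FP + c.TP),
        "recall": (c.TP, c.FN + c.TP),
        "specificity": (c.TN, c.TN + c.FP),
        "f1": (c.TP, c.TP + (c.FP + c.FN) / 2.0),
    }
    if metric not in num_den:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRIC_NAMES}")
    num, den = num_den[metric]
    return num / den if den > 0 else float("nan")


def bootstrap_ci(
    y_true: Sequence,
    y_pred: Sequence,
    metric: str | Callable[[np.ndarray, np.ndarray], float] = "accuracy",
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    positive=POSITIVE_LABEL,
) -> BootstrapCi:
    """Percentile bootstrap CI for a metric of pooled predictions.

    Replicates on which the metric is undefined (e.g. no positives drawn)
    are skipped and counted; a warning is attached when more than 10% of
    replicates were skipped.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.size < 1:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    if B < 100:
        raise ValueError("B must be >= 100 for a percentile interval")
    if callable(metric):
        fn = metric
        name = getattr(metric, "__name__", "custom")
    else:
        name = metric
        fn = lambda a, b: metric_value(a, b, name, positive)
    point = float(fn(yt, yp))
    rng = np.random.default_rng(seed)
    n = yt.size
    values = np.empty(B)
    for r in range(B):
        idx = rng.integers(0, n, n)
        values[r] = fn(yt[idx], yp[idx])
    ok = np.isfinite(values)
    skipped = int(B - ok.sum())
    if skipped > 0.1 * B:
        warnings.warn(
            f"bootstrap_ci({name}): {skipped}/{B} replicates undefined and skipped"
        )
    if ok.sum() == 0:
        raise ValueError("metric undefined on every bootstrap replicate")
    alpha = 1.0 - level
    lo, hi = np.percentile(values[ok], [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCi(
        metric=name,
        point=point,
        mean=float(values[ok].mean()),
        lower=float(lo),
        upper=float(hi),
        B=B,
        level=level,
        seed=seed,
        skipped=skipped,
    )


def mcnemar_test(
    pred_a: Sequence,
    pred_b: Sequence,
    y_true: Sequence,
    folds: Sequence | None = None,
    level: float = 0.95,
    mode: str = "exact",
) -> McNemarResult:
    """Exact McNemar comparison of two prediction vectors on the same
    samples.

    ``b`` counts samples where only classifier A is correct, ``c`` where
    only B is.  With ``folds`` given, the per-fold difference ``b - c`` is
    summarized by its mean and a percentile interval across folds.

    ``mode="exact"`` (default) is the doubled-binomial exact p, which is
    guaranteed valid but conservative because the discordant count is
    discrete; ``mode="midp"`` halves the probability of the observed
    count (the mid-p variant), trading the guarantee for a null
    distribution much closer to uniform.
    """
    pa = np.asarray(pred_a)
    pb = np.asarray(pred_b)
    yt = np.asarray(y_true)
    if not (pa.shape == pb.shape == yt.shape):
        raise ValueError("prediction vectors and labels must be equal-length")
    correct_a = pa == yt
    correct_b = pb == yt
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if b + c == 0:
        p = 1.0
        no_disc = True
    else:
        k, m = min(b, c), b + c
        if mode == "exact":
            p = min(1.0, 2.0 * float(stats.binom.cdf(k, m, 0.5)))
        elif mode == "midp":
            p = min(
                1.0,
                2.0
                * float(stats.binom.cdf(k - 1, m, 0.5) + 0.5 * stats.binom.pmf(k, m, 0.5)),
            )
        else:
            raise ValueError(f"unknown mode {mode!r}; expected 'exact' or 'midp'")
        no_disc = False
    difference = None
    ci = None
    if folds is not None:
        folds = np.asarray(folds)
        diffs = []
        for f in np.unique(folds):
            m = folds == f
            bf = int(np.sum(correct_a[m] & ~correct_b[m]))
            cf = int(np.sum(~correct_a[m] & correct_b[m]))
            diffs.append(bf - cf)
        alpha = 1.0 - level
        difference = float(np.mean(diffs))
        ci = tuple(
            float(v)
            for v in np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        )
    return McNemarResult(b=b, c=c, p_value=p, difference=difference, ci=ci, no_discordance=no_disc)


def pairwise_compare(runs: Sequence[CvRun], level: float = 0.95) -> pd.DataFrame:
    """All unordered pairwise McNemar comparisons between classifier runs
    sharing one fold plan.

    Returns a table with one row per pair: ``pair, b, c, difference,
    ci_lower, ci_upper, p_value``.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to compare")
    ref = runs[0]
    for run in runs[1:]:
        if run.plan.k != ref.plan.k or not np.array_equal(
            run.plan.assignments, ref.plan.assignments
        ):
            raise ValueError("all runs must share the same fold plan")
        if not np.array_equal(
            run.predictions["y_true"].to_numpy(), ref.predictions["y_true"].to_numpy()
        ):
            raise ValueError("all runs must be evaluated on identical samples")
    rows = []
    for ra, rb in itertools.combinations(runs, 2):
        res = mcnemar_test(
            ra.predictions["y_pred"].to_numpy(),
            rb.predictions["y_pred"].to_numpy(),
            ra.predictions["y_true"].to_numpy(),
            folds=ra.predictions["fold"].to_numpy(),
            level=level,
        )
        rows.append(
            dict(
                pair=f"{ra.kind} vs {rb.kind}",
                b=res.b,
                c=res.c,
                difference=res.difference,
                ci_lower=res.ci[0],
                ci_upper=res.ci[1],
                p_value=res.p_value,
            )
        )
    return pd.DataFrame(rows)
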