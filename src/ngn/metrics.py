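"""Evaluation statistics for classification, regression and toxicology runs.

Classification: concordance Q, sensitivity SE, specificity SP and Matthews
correlation coefficient MCC from a confusion matrix.  Regression: the
predictive residual sum of squares PRESS, the sum of squared deviations SD
of the test targets from their own mean, and q2 = 1 - PRESS/SD (SD is
computed on the test set only).  Toxicology: Epsilon, the per-trial sum of
absolute residuals between normalized targets and network outputs, its
standard deviation, the Pearson correlation between known and estimated
values, and a Wilcoxon signed-rank test for paired method comparison.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DataError, UndefinedStatisticError

POS, NEG = "pos", "neg"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class RegressionEval:
    press: float
    sd: float
    q2: float


@dataclass(frozen=True)
class ToxStats:
    epsilon: float
    epsilon_sd: float
    cc: float | None = None


def confusion_from_predictions(preds, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Count the confusion matrix; a prediction >= threshold is positive."""
    preds = list(preds)
    labels = list(labels)
    if len(preds) != len(labels):
        raise DataError(f"{len(preds)} predictions vs {len(labels)} labels")
    if not (0.0 < threshold < 1.0):
        raise DataError(f"threshold must be in (0, 1), got {threshold}")
    tp = tn = fp = fn = 0
    for p, lab in zip(preds, labels):
        predicted_pos = bool(p >= threshold)
        if lab == POS:
            tp, fn = tp + predicted_pos, fn + (not predicted_pos)
        elif lab == NEG:
            fp, tn = fp + predicted_pos, tn + (not predicted_pos)
        else:
            raise DataError(f"label must be 'pos' or 'neg', got {lab!r}")
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Q, SE, SP and MCC.  MCC is 0 by convention when a denominator factor
    vanishes; SE/SP are NaN when no positives/negatives exist."""
    if c.total == 0:
        raise DataError("empty confusion counts")
    q = (c.tp + c.tn) / c.total
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    return {"Q": q, "SE": se, "SP": sp, "MCC": mcc}


def regression_q2(preds, targets) -> RegressionEval:
    p = np.asarray(preds, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise DataError("prediction/target length mismatch")
    if t.size < 2:
        raise DataError("q2 needs at least two exemplars")
    press = float(np.sum((t - p) ** 2))
    sd = float(np.sum((t - t.mean()) ** 2))
    if sd == 0.0:
        raise UndefinedStatisticError("q2 undefined: all targets identical")
    return RegressionEval(press=press, sd=sd, q2=1.0 - press / sd)


def epsilon_stats(preds, targets, *, signed: bool = False) -> ToxStats:
    """Per-trial summed residual (Epsilon) and its standard deviation.

    Absolute residuals by default, so a smaller Epsilon always means
    smaller residuals; ``signed=True`` sums raw differences instead.
    For a single pair the sample standard deviation is reported as 0.
    """
    p = np.asarray(preds, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise DataError("prediction/target length mismatch")
    if p.size == 0:
        raise DataError("empty inputs")
    r = (t - p) if signed else np.abs(t - p)
    eps = float(np.sum(r))
    sd = float(np.std(np.abs(t - p), ddof=1)) if p.size > 1 else 0.0
    return ToxStats(epsilon=eps, epsilon_sd=sd)


def pearson_cc(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("length mismatch")
    if x.size < 2:
        raise DataError("correlation needs at least two pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def normalize_targets(values, lo: float = 0.2, hi: float = 0.8) -> np.ndarray:
    """Min-max scaling ``val -> lo + (hi-lo)*(val-min)/(max-min)``.

    The dataset minimum maps exactly to ``lo`` and the maximum to ``hi``;
    the map is affine hence order-preserving.
    """
    v = np.asarray(values, dtype=float)
    if lo >= hi:
        raise DataError(f"need lo < hi, got ({lo}, {hi})")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        raise DataError("degenerate range: all values identical")
    u = (v - vmin) / (vmax - vmin)
    # convex combination rather than lo + (hi-lo)*u so the endpoints land on
    # lo and hi exactly in floating point
    return lo * (1.0 - u) + hi * u


def label_by_threshold(activities, theta: float, *, positive_above: bool = True) -> list[str]:
    """Threshold labeling: activity >= theta is positive (tie goes to
    positive); ``positive_above=False`` complements the direction."""
    out = []
    for a in activities:
        hit = a >= theta
        out.append(POS if hit == positive_above else NEG)
    return out


# ---------------------------------------------------------------------- #
# Wilcoxon signed-rank

EXACT_N_MAX = 12


@dataclass(frozen=True)
class WilcoxonResult:
    W: float          # sum of ranks of positive differences (W+)
    p: float
    n_used: int       # pairs remaining after dropping zero differences
    method: str       # "exact" or "normal"


def wilcoxon_signed_rank(a, b, *, alternative: str = "two-sided") -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences receive average
    ranks.  The null distribution of W+ is enumerated exactly over all sign
    patterns for n <= 12 and approximated normally (with tie correction and
    continuity correction) above.  ``alternative`` is ``two-sided``,
    ``greater`` (differences a-b tend positive) or ``less``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise DataError("paired samples must be equal-length and non-empty")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedStatisticError("all differences are zero: no information")
    ranks = rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    total = float(np.sum(ranks))
    mu = total / 2.0

    if n <= EXACT_N_MAX:
        # exact: distribution of W+ over the 2^n equiprobable sign patterns
        ge = le = 0
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            ge += w >= w_plus
            le += w <= w_plus
            count += 1
        p_greater = ge / count
        p_less = le / count
        # symmetric about mu (flipping all signs maps W+ to total - W+)
        p_two = min(1.0, 2.0 * min(p_greater, p_less))
        method = "exact"
    else:
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
        sd = math.sqrt(var)
        z_greater = (w_plus - mu - 0.5) / sd
        z_less = (w_plus - mu + 0.5) / sd
        p_greater = float(norm.sf(z_greater))
        p_less = float(norm.cdf(z_less))
        p_two = min(1.0, 2.0 * min(p_greater, p_less))
        method = "normal"

    p = {"two-sided": p_two, "greater": p_greater, "less": p_less}.get(alternative)
    if p is None:
        raise DataError(f"unknown alternative {alternative!r}")
    return WilcoxonResult(W=w_plus, p=p, n_used=n, method=method)
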