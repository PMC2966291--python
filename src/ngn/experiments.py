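"""Cross-validation designs, repeated trials and the descriptor-ANN baseline.

Designs: Leave-20%-Out (5 folds x 10 repetitions = 50 trials, the
classification design), Leave-5%-Out (20 folds x 1 = 20 trials, the
regression design), explicit designed train/test splits (10 trials),
grouped five-fold (sort by target, deal round-robin into 5 clusters evenly
spread over the output range) and random five-fold (a fresh random fifth
per trial).  Aggregates are reported as mean +/- sample standard deviation
over converged trials only; non-converged trials are flagged and excluded.

The baseline is a plain fully-connected logistic network over transparent
string-computable token-count descriptors, trained under the same
convergence/restart contract as the NGN, for paired Wilcoxon comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TrainingConfig
from .errors import DataError, DesignError, UndefinedStatisticError
from .grammar import Grammar
from .metrics import (
    POS,
    classification_metrics,
    confusion_from_predictions,
    epsilon_stats,
    pearson_cc,
    regression_q2,
    wilcoxon_signed_rank,
)
from .network import predict_many, train
from .parse import parse_string, tokenize

SCHEMES = ("leave20_cv", "leave5_cv", "designed", "grouped5", "random5")


@dataclass
class FoldPlan:
    scheme: str
    folds: list[np.ndarray]          # test-index sets
    reps_per_fold: int
    seed: int
    n: int
    n_random_trials: int = 0         # random5 only

    @property
    def n_trials(self) -> int:
        if self.scheme == "random5":
            return self.n_random_trials
        return len(self.folds) * self.reps_per_fold

    def trial_split(self, trial: int, rng: np.random.Generator):
        """Test/train indices for one trial."""
        if self.scheme == "random5":
            test = rng.choice(self.n, size=self.n // 5, replace=False)
        else:
            test = self.folds[trial % len(self.folds)]
        mask = np.ones(self.n, dtype=bool)
        mask[test] = False
        return np.asarray(test), np.nonzero(mask)[0]


def make_folds(n: int, scheme: str, targets=None, seed: int = 0,
               reps_per_fold: int | None = None, n_trials: int | None = None,
               test_indices=None) -> FoldPlan:
    """Build a fold plan for one of the standard designs."""
    if scheme not in SCHEMES:
        raise DesignError(f"unknown scheme {scheme!r}; available: {SCHEMES}")
    rng = np.random.default_rng(seed)

    if scheme == "designed":
        if test_indices is None:
            raise DesignError("designed scheme needs explicit test_indices")
        test = np.asarray(sorted(test_indices), dtype=int)
        if test.size == 0 or test.size >= n:
            raise DesignError("designed test set must be a proper non-empty subset")
        return FoldPlan(scheme, [test], reps_per_fold or 10, seed, n)

    k = 5 if scheme in ("leave20_cv", "grouped5", "random5") else 20
    if n < k:
        raise DesignError(f"{scheme} needs at least {k} exemplars, got {n}")

    if scheme == "random5":
        return FoldPlan(scheme, [], 1, seed, n,
                        n_random_trials=n_trials if n_trials is not None else 50)

    if scheme == "grouped5":
        if targets is None:
            raise DesignError("grouped5 needs targets")
        order = np.argsort(np.asarray(targets, dtype=float), kind="stable")
        folds = [order[c::5].copy() for c in range(5)]
        default_reps = 10
    else:
        perm = rng.permutation(n)
        folds = [np.sort(f) for f in np.array_split(perm, k)]
        default_reps = 10 if scheme == "leave20_cv" else 1
    reps = default_reps if reps_per_fold is None else reps_per_fold
    return FoldPlan(scheme, folds, reps, seed, n)


# ---------------------------------------------------------------------- #
# trial running


@dataclass
class EvaluationReport:
    """Per-trial metric records plus converged-only aggregates."""

    task: str
    trials: pd.DataFrame
    n_trials: int
    n_converged: int
    aggregates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"{self.task} report: {self.n_converged}/{self.n_trials} trials converged"
        ]
        for name, (mean, sd) in self.aggregates.items():
            lines.append(f"  {name:10s} {mean:.3f} +/- {sd:.3f}")
        return "\n".join(lines)


_CLS_METRICS = ("Q", "SE", "SP", "MCC")
_REG_METRICS = ("q2", "press", "epsilon", "epsilon_sd")


def run_trials(dataset, g: Grammar, cfg: TrainingConfig, plan: FoldPlan,
               task: str = "classification", *, engine: str = "fast",
               threshold: float | None = None) -> EvaluationReport:
    """Train/evaluate over every trial of a fold plan.

    Each trial gets a fresh library seeded from (plan seed, trial index),
    trains on the train fold and is scored on the test fold; the whole run
    is reproducible from (seed, plan, config).  Classification datasets are
    (string, 'pos'/'neg') pairs; regression datasets are (string, target in
    the output scale).
    """
    if task not in ("classification", "regression"):
        raise DesignError(f"unknown task {task!r}")
    strings = [s for s, _ in dataset]
    if len(strings) != plan.n:
        raise DesignError(f"plan built for n={plan.n}, dataset has {len(strings)}")
    if task == "classification":
        raw = [y for _, y in dataset]
        targets = np.where([y == POS for y in raw], cfg.output_hi, cfg.output_lo)
        labels = list(raw)
    else:
        targets = np.asarray([y for _, y in dataset], dtype=float)
        labels = None
    if threshold is None:
        threshold = cfg.output_mid
    trees = [parse_string(s, g) for s in strings]

    rows = []
    for trial in range(plan.n_trials):
        trial_rng = np.random.default_rng(np.random.SeedSequence([plan.seed, trial]))
        test_idx, train_idx = plan.trial_split(trial, trial_rng)
        trial_seed = int(trial_rng.integers(2**31 - 1))
        lib, res = train(
            [(strings[i], targets[i]) for i in train_idx], g, cfg,
            seed=trial_seed, engine=engine,
            trees=[trees[i] for i in train_idx],
        )
        row = {
            "trial": trial,
            "fold": trial % len(plan.folds) if plan.folds else -1,
            "converged": res.converged,
            "epochs": res.epochs,
            "restarts": res.restarts,
            "train_rmse": res.final_rmse,
        }
        preds = predict_many(lib, [strings[i] for i in test_idx], g)
        if task == "classification":
            cm = confusion_from_predictions(
                preds, [labels[i] for i in test_idx], threshold
            )
            row.update(classification_metrics(cm))
        else:
            tt = targets[test_idx]
            try:
                row["q2"] = regression_q2(preds, tt).q2
                row["press"] = regression_q2(preds, tt).press
            except UndefinedStatisticError:
                row["q2"] = np.nan
                row["press"] = np.nan
            tox = epsilon_stats(preds, tt)
            row["epsilon"] = tox.epsilon
            row["epsilon_sd"] = tox.epsilon_sd
            try:
                row["cc"] = pearson_cc(tt, preds)
            except UndefinedStatisticError:
                row["cc"] = np.nan
        rows.append(row)

    trials = pd.DataFrame(rows)
    conv = trials[trials["converged"]]
    metric_cols = _CLS_METRICS if task == "classification" else _REG_METRICS
    aggregates = {}
    for col in metric_cols:
        if col in trials.columns and len(conv):
            vals = conv[col].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            aggregates[col] = (float(np.mean(vals)), sd)
    return EvaluationReport(
        task=task, trials=trials, n_trials=len(trials),
        n_converged=int(trials["converged"].sum()), aggregates=aggregates,
    )


# ---------------------------------------------------------------------- #
# token-count descriptor baseline

_ELEMENTS = ("B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I",
             "b", "c", "n", "o", "p", "s")
_BONDS = ("-", "=", "#", "/", "\\")

DESCRIPTOR_NAMES = (
    tuple(f"n_{e}" for e in _ELEMENTS)
    + ("n_branch", "n_ring_digit")
    + tuple(f"n_bond_{b}" for b in _BONDS)
    + ("n_tokens",)
)


def descriptor_vector(s: str, g: Grammar) -> np.ndarray:
    """Fixed-length token-count descriptors: per-element counts, branch
    openings, ring-closure digits, per-bond-symbol counts, total tokens.

    These deliberately discard *where* in the traversal a feature occurs —
    the information the grammar-structured network retains."""
    texts = [t.text for t in tokenize(s, g)]
    v = [float(texts.count(e)) for e in _ELEMENTS]
    v.append(float(texts.count("(")))
    v.append(float(sum(1 for t in texts if t.isdigit())))
    v.extend(float(texts.count(b)) for b in _BONDS)
    v.append(float(len(texts)))
    return np.array(v)


@dataclass
class BaselineANN:
    """A 3-layer fully-connected logistic network (trained weights)."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    x_lo: np.ndarray
    x_span: np.ndarray
    converged: bool = True
    epochs: int = 0
    restarts: int = 0
    final_rmse: float = np.nan


ANN_DEFAULTS = dict(hidden=2, eta=0.9, momentum=0.3, init=0.3,
                    max_epochs=50_000, rmse_threshold=0.05, max_restarts=3)


def _ann_forward(model: BaselineANN, x: np.ndarray):
    h = 1.0 / (1.0 + np.exp(-(model.w1 @ x + model.b1)))
    o = 1.0 / (1.0 + np.exp(-(model.w2 @ h + model.b2)))
    return h, float(o[0])


def baseline_ann_train(vectors, targets, *, seed: int = 0, **params) -> BaselineANN:
    """Online gradient descent with momentum to an RMSE threshold.

    Same convergence/restart contract as the NGN trainer.  Inputs are
    min-max scaled to [0, 1] feature-wise on the training set (constant
    features map to 0)."""
    p = dict(ANN_DEFAULTS)
    p.update(params)
    X = np.asarray(vectors, dtype=float)
    t = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[0] != t.size:
        raise DataError("vectors/targets shape mismatch")
    x_lo = X.min(axis=0)
    x_span = X.max(axis=0) - x_lo
    x_span[x_span == 0] = 1.0
    Xs = (X - x_lo) / x_span
    n, d = Xs.shape
    h = p["hidden"]

    model = None
    for attempt in range(p["max_restarts"] + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, attempt]))
        w1 = rng.uniform(-p["init"], p["init"], size=(h, d))
        b1 = rng.uniform(-p["init"], p["init"], size=h)
        w2 = rng.uniform(-p["init"], p["init"], size=(1, h))
        b2 = rng.uniform(-p["init"], p["init"], size=1)
        dw1 = np.zeros_like(w1); db1 = np.zeros_like(b1)
        dw2 = np.zeros_like(w2); db2 = np.zeros_like(b2)
        model = BaselineANN(w1, b1, w2, b2, x_lo, x_span)
        converged = False
        epochs = 0
        rmse = np.nan
        for epoch in range(p["max_epochs"]):
            order = rng.permutation(n)
            sse = 0.0
            for i in order:
                x = Xs[i]
                hid, out = _ann_forward(model, x)
                err = t[i] - out
                sse += err * err
                d_out = err * out * (1 - out)
                d_hid = hid * (1 - hid) * (w2[0] * d_out)
                u2 = p["eta"] * d_out * hid[None, :] + p["momentum"] * dw2
                ub2 = p["eta"] * np.array([d_out]) + p["momentum"] * db2
                u1 = p["eta"] * np.outer(d_hid, x) + p["momentum"] * dw1
                ub1 = p["eta"] * d_hid + p["momentum"] * db1
                w2 += u2; b2 += ub2; w1 += u1; b1 += ub1
                dw2, db2, dw1, db1 = u2, ub2, u1, ub1
            rmse = float(np.sqrt(sse / n))
            epochs = epoch + 1
            if rmse < p["rmse_threshold"]:
                converged = True
                break
        model.converged = converged
        model.epochs = epochs
        model.restarts = attempt
        model.final_rmse = rmse
        if converged:
            break
    return model


def baseline_ann_predict(model: BaselineANN, vector) -> float:
    x = (np.asarray(vector, dtype=float) - model.x_lo) / model.x_span
    return _ann_forward(model, x)[1]


# ---------------------------------------------------------------------- #
# paired comparison


@dataclass(frozen=True)
class MethodComparison:
    W: float
    p: float
    winner: str          # "a", "b" or "none"
    n_used: int
    statistic: str


def compare_methods(report_a: EvaluationReport, report_b: EvaluationReport,
                    statistic: str = "epsilon",
                    alpha: float = 0.05) -> MethodComparison:
    """Paired Wilcoxon signed-rank comparison of two trial reports.

    Trials are matched by position (same fold/rep structure required);
    smaller values of the statistic are better, and the winner is declared
    when the one-sided p in the observed direction is below ``alpha``."""
    if statistic not in ("epsilon", "epsilon_sd", "press"):
        raise DesignError(f"unsupported comparison statistic {statistic!r}")
    a = report_a.trials[statistic].to_numpy(dtype=float)
    b = report_b.trials[statistic].to_numpy(dtype=float)
    if a.shape != b.shape:
        raise DesignError("reports have mismatched trial structure")
    try:
        lead_a = float(np.median(a - b)) < 0 or float(np.sum(a - b)) < 0
        res = wilcoxon_signed_rank(a, b, alternative="less" if lead_a else "greater")
    except UndefinedStatisticError:
        return MethodComparison(W=np.nan, p=1.0, winner="none",
                                n_used=0, statistic=statistic)
    winner = "none"
    if res.p < alpha:
        winner = "a" if lead_a else "b"
    return MethodComparison(W=res.W, p=res.p, winner=winner,
                            n_used=res.n_used, statistic=statistic)
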