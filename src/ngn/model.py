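"""Model-object front end: NeuralGrammarNetwork / NGNResults.

The model is constructed from molecular strings plus targets or class
labels and a grammar; ``fit`` trains the shared weight-layer library by
backpropagation through structure and returns an :class:`NGNResults`
carrying the trained library, convergence diagnostics, training-set
goodness of fit, prediction, a ``summary()`` table and a convergence plot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import TrainingConfig
from .errors import DataError
from .grammar import Grammar, builtin_grammar
from .metrics import (
    NEG,
    POS,
    classification_metrics,
    confusion_from_predictions,
    regression_q2,
)
from .network import TrainingResult, WeightLayerLibrary, predict_many, train
from .parse import parse_string


class NeuralGrammarNetwork:
    """A grammar-structured recursive neural network over molecular strings.

    Parameters
    ----------
    strings : sequence of str
        Molecules in the grammar's line notation (SMILES by default).
    targets : sequence of float, optional
        Regression targets, already scaled into the configured output
        range (see :func:`ngn.metrics.normalize_targets`).
    labels : sequence of {"pos", "neg"}, optional
        Class labels; mapped onto the output-scale endpoints.
    grammar : Grammar or builtin name, default "smiles_extended"
    config : TrainingConfig, optional
        Defaults to the classification preset.

    Exactly one of ``targets``/``labels`` must be given.  All strings are
    parsed at construction; the parse trees are reused across epochs and
    restarts.
    """

    def __init__(self, strings, targets=None, labels=None,
                 grammar: Grammar | str = "smiles_extended",
                 config: TrainingConfig | None = None):
        if (targets is None) == (labels is None):
            raise DataError("provide exactly one of targets / labels")
        self.grammar = builtin_grammar(grammar) if isinstance(grammar, str) else grammar
        self.config = config if config is not None else TrainingConfig()
        self.strings = [str(s) for s in strings]
        if not self.strings:
            raise DataError("empty dataset")
        self.task = "regression" if labels is None else "classification"
        if self.task == "classification":
            labels = list(labels)
            if len(labels) != len(self.strings):
                raise DataError("strings/labels length mismatch")
            bad = [x for x in labels if x not in (POS, NEG)]
            if bad:
                raise DataError(f"labels must be 'pos'/'neg', got {bad[:3]}")
            self.labels = labels
            self.targets = np.where(
                np.array(labels) == POS, self.config.output_hi, self.config.output_lo
            )
        else:
            self.labels = None
            self.targets = np.asarray(list(targets), dtype=float)
            if self.targets.size != len(self.strings):
                raise DataError("strings/targets length mismatch")
        self.trees = []
        for s in self.strings:
            try:
                self.trees.append(parse_string(s, self.grammar))
            except Exception as exc:
                raise DataError(f"molecule {s!r} does not parse: {exc}") from exc

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, molecule_col: str = "molecule",
                       target_col: str | None = None, label_col: str | None = None,
                       **kwargs) -> "NeuralGrammarNetwork":
        """Build from a DataFrame with molecule and target/label columns."""
        if molecule_col not in df.columns:
            raise DataError(f"missing column {molecule_col!r}")
        if target_col is None and label_col is None:
            if "target" in df.columns:
                target_col = "target"
            elif "label" in df.columns:
                label_col = "label"
            else:
                raise DataError("no target or label column found")
        strings = df[molecule_col].astype(str).tolist()
        if label_col is not None:
            return cls(strings, labels=df[label_col].astype(str).tolist(), **kwargs)
        return cls(strings, targets=df[target_col].astype(float).to_numpy(), **kwargs)

    def fit(self, seed: int | None = None, engine: str = "fast",
            log=None) -> "NGNResults":
        """Train to the configured RMSE threshold (with restarts)."""
        dataset = list(zip(self.strings, self.targets))
        lib, res = train(dataset, self.grammar, self.config, seed=seed,
                         engine=engine, trees=self.trees, log=log)
        return NGNResults(self, lib, res, seed=self.config.seed if seed is None else seed)


class NGNResults:
    """Fit results: the trained weight-layer library plus diagnostics."""

    def __init__(self, model: NeuralGrammarNetwork, library: WeightLayerLibrary,
                 training: TrainingResult, seed: int):
        self.model = model
        self.library = library
        self.training = training
        self.seed = seed

    # convenience passthroughs
    @property
    def converged(self) -> bool:
        return self.training.converged

    @property
    def final_rmse(self) -> float:
        return self.training.final_rmse

    def predict(self, strings=None) -> np.ndarray:
        """Network outputs in (0, 1) for new strings (training set if None)."""
        if strings is None:
            strings = self.model.strings
        return predict_many(self.library, strings, self.model.grammar)

    def predict_labels(self, strings=None, threshold: float | None = None) -> list[str]:
        if threshold is None:
            threshold = self.model.config.output_mid
        return [POS if p >= threshold else NEG for p in self.predict(strings)]

    def fit_metrics(self) -> dict[str, float]:
        """Training-set goodness of fit (Q/SE/SP/MCC or q2)."""
        preds = self.predict()
        if self.model.task == "classification":
            cm = confusion_from_predictions(
                preds, self.model.labels, self.model.config.output_mid
            )
            return classification_metrics(cm)
        ev = regression_q2(preds, self.model.targets)
        return {"q2": ev.q2, "PRESS": ev.press, "SD": ev.sd}

    def save(self, path) -> None:
        from .io import save_model

        save_model(path, self.library)

    def summary(self) -> str:
        m = self.model
        t = self.training
        lines = [
            "Neural Grammar Network fit",
            "=" * 44,
            f"grammar:        {m.grammar.name} ({len(m.grammar.rules)} rules)",
            f"task:           {m.task}",
            f"n exemplars:    {len(m.strings)}",
            f"sharing mode:   {m.config.sharing_mode}",
            f"library size:   {len(self.library)} weight layers",
            f"hidden size:    {m.config.hidden_size}",
            f"eta / momentum: {m.config.eta} / {m.config.momentum_alpha}",
            f"seed:           {self.seed}",
            "-" * 44,
            f"converged:      {t.converged} "
            f"(epochs={t.epochs}, restarts={t.restarts})",
            f"final RMSE:     {t.final_rmse:.4f} "
            f"(threshold {m.config.rmse_threshold})",
        ]
        for k, v in self.fit_metrics().items():
            lines.append(f"{k + ':':15s} {v:.4f}")
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Per-epoch training RMSE of the final attempt."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = self.training.rmse_history
        ax.plot(range(1, len(hist) + 1), hist, lw=1)
        ax.axhline(self.model.config.rmse_threshold, ls="--", color="grey",
                   label="convergence threshold")
        ax.set_xlabel("epoch")
        ax.set_ylabel("training RMSE")
        ax.set_title("NGN training convergence")
        ax.legend()
        return ax
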