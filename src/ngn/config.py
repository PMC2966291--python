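"""Run configuration: training hyperparameters and named presets.

The presets are the parameter sets used for the package's standard
experiment designs:

================== ====== ===== ===== ========= ============ ======= ======
preset             eta    alpha RMSE  epochs    init bands   hidden  scale
================== ====== ===== ===== ========= ============ ======= ======
classification     0.60   0.90  0.05  5000      [1.0, 1.6]   8       0.2-0.8
regression_cv      0.30   0.10  0.03  7500      [1.0, 1.6]   8       0.2-0.8
regression_designed 0.33  0.66  0.04  7500      [0.4, 1.2]   8       0.2-0.8
toxicology_ngn     0.30   0.30  0.05* 10000     [1.0, 1.6]   12      0.2-0.8
================== ====== ===== ===== ========= ============ ======= ======

(*) the toxicology design uses two thresholds: 0.05 for training runs and a
stricter 0.03 convergence pre-test, kept as distinct fields.  Initial
weights are drawn from the symmetric two-band range
[-init_high, -init_low] u [init_low, init_high].
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from .errors import ConfigError

SHARING_MODES = ("per_symbol_pair", "per_rule")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one NGN training run."""

    eta: float = 0.60                # training constant
    momentum_alpha: float = 0.90     # fraction of the previous delta carried over
    rmse_threshold: float = 0.05     # epoch RMSE below this => converged
    max_epochs: int = 5000           # per restart, before giving up
    max_restarts: int = 3            # re-initializations after max_epochs
    hidden_size: int | dict = 8      # units per internal symbol (global or per-name)
    init_low: float = 1.0
    init_high: float = 1.6
    output_lo: float = 0.2           # targets live in (output_lo, output_hi)
    output_hi: float = 0.8
    seed: int = 0
    sharing_mode: str = "per_symbol_pair"
    pretest_rmse_threshold: float | None = None  # convergence pre-test, if used

    def __post_init__(self):
        if not (0.0 < self.output_lo < self.output_hi < 1.0):
            raise ConfigError(
                f"output scale must satisfy 0 < lo < hi < 1, got "
                f"({self.output_lo}, {self.output_hi})"
            )
        if not (0.0 < self.init_low < self.init_high):
            raise ConfigError(
                f"init bands must satisfy 0 < low < high, got "
                f"[{self.init_low}, {self.init_high}]"
            )
        if self.eta <= 0:
            raise ConfigError(f"eta must be positive, got {self.eta}")
        if not (0.0 <= self.momentum_alpha < 1.0):
            raise ConfigError(
                f"momentum_alpha must be in [0, 1), got {self.momentum_alpha}"
            )
        if self.max_epochs < 1:
            raise ConfigError(f"max_epochs must be positive, got {self.max_epochs}")
        if self.max_restarts < 0:
            raise ConfigError(f"max_restarts must be >= 0, got {self.max_restarts}")
        if self.rmse_threshold <= 0:
            raise ConfigError(f"rmse_threshold must be positive, got {self.rmse_threshold}")
        if self.sharing_mode not in SHARING_MODES:
            raise ConfigError(
                f"sharing_mode must be one of {SHARING_MODES}, got {self.sharing_mode!r}"
            )
        if isinstance(self.hidden_size, int):
            if self.hidden_size < 1:
                raise ConfigError(f"hidden_size must be positive, got {self.hidden_size}")
        else:
            for k, v in self.hidden_size.items():
                if not isinstance(v, int) or v < 1:
                    raise ConfigError(f"hidden_size[{k!r}] must be a positive int")

    def hsize(self, symbol_name: str) -> int:
        """Hidden-layer width for one internal symbol."""
        if isinstance(self.hidden_size, int):
            return self.hidden_size
        return self.hidden_size.get(symbol_name, self.hidden_size.get("default", 8))

    def replace(self, **changes) -> "TrainingConfig":
        return dataclasses.replace(self, **changes)

    @property
    def output_mid(self) -> float:
        """Classification decision threshold: the midpoint of the output scale."""
        return 0.5 * (self.output_lo + self.output_hi)


PRESETS: dict[str, dict] = {
    "classification": dict(),  # the defaults above
    "regression_cv": dict(
        eta=0.30, momentum_alpha=0.10, rmse_threshold=0.03, max_epochs=7500
    ),
    "regression_designed": dict(
        eta=0.33, momentum_alpha=0.66, rmse_threshold=0.04, max_epochs=7500,
        init_low=0.4, init_high=1.2,
    ),
    "toxicology_ngn": dict(
        eta=0.30, momentum_alpha=0.30, rmse_threshold=0.05,
        pretest_rmse_threshold=0.03, max_epochs=10000, hidden_size=12,
    ),
}


def preset(name: str, **overrides) -> TrainingConfig:
    """A named preset, optionally with field overrides."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return TrainingConfig(**kw)


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(TrainingConfig)}


def load_config(path_or_text: str) -> tuple[TrainingConfig, dict]:
    """Read a YAML/JSON config document.

    Returns ``(TrainingConfig, extras)`` where extras holds any
    experiment-level settings (scheme, reps, grammar, ...) that are not
    TrainingConfig fields.  A ``preset`` key selects defaults; explicit
    fields override it; an empty document yields the classification
    defaults.
    """
    import os

    import yaml

    if os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    else:
        text = path_or_text
    doc = yaml.safe_load(text) if text.strip() else {}
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    doc = dict(doc)
    base = doc.pop("preset", "classification")
    fields = {k: v for k, v in doc.items() if k in _CONFIG_FIELDS}
    extras = {k: v for k, v in doc.items() if k not in _CONFIG_FIELDS}
    try:
        cfg = preset(base, **fields)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg, extras


def config_to_json(cfg: TrainingConfig) -> str:
    return json.dumps(dataclasses.asdict(cfg), sort_keys=True)
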