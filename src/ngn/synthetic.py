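"""Grammar-valid synthetic datasets with controllable structure.

Strings are sampled by stochastic leftmost derivation: at each internal
symbol a production is drawn uniformly among those whose minimal completion
still fits the remaining depth budget, so generation always terminates and
every emitted string parses under the generating grammar.  Labeling rules
turn strings into classification or regression tasks that stand in for
curated QSAR datasets when exercising the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GenerationError
from .grammar import Grammar, KIND_ACCEPTANCE
from .metrics import NEG, POS, normalize_targets
from .parse import tokenize

LABEL_RULES = (
    "contains_token",
    "substring_presence",
    "token_count_threshold",
    "scaled_token_count",
)


@dataclass(frozen=True)
class SynthTask:
    """Specification of one synthetic dataset.

    ``param`` is the token or substring the rule inspects; ``threshold``
    is the count cutoff for ``token_count_threshold``.
    """

    kind: str                       # classification | regression
    label_rule: str
    param: str
    n: int
    max_depth: int = 14
    noise_sd: float = 0.0
    threshold: int = 2
    seed: int = 0
    balance: tuple[float, float] = (0.4, 0.6)

    def __post_init__(self):
        if self.kind not in ("classification", "regression"):
            raise GenerationError(f"unknown task kind {self.kind!r}")
        if self.label_rule not in LABEL_RULES:
            raise GenerationError(f"unknown label rule {self.label_rule!r}")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")


def _min_depths(g: Grammar) -> dict[str, int]:
    """Minimal derivation depth (levels of internal nodes) per symbol."""
    inf = float("inf")
    depth = {name: inf for name in g.internal_symbols}
    changed = True
    while changed:
        changed = False
        for r in g.rules:
            if r.kind == KIND_ACCEPTANCE:
                d = 1
            else:
                worst = 0
                for sym in r.rhs:
                    worst = max(worst, depth[sym.name] if sym.is_internal else 0)
                d = 1 + worst
            if d < depth[r.lhs.name]:
                depth[r.lhs.name] = d
                changed = True
    return depth


def sample_string(g: Grammar, max_depth: int,
                  seed: int | np.random.Generator = 0) -> str:
    """One stochastic leftmost derivation; always parses under ``g``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depth = g.__dict__.setdefault("_min_depth_cache", _min_depths(g))
    if depth[g.start.name] > max_depth:
        raise GenerationError(
            f"no derivation of {g.start.name!r} fits depth {max_depth}"
        )

    out: list[str] = []

    def expand(symbol_name: str, budget: int):
        viable = []
        for r in g.rules_for(symbol_name):
            if r.kind == KIND_ACCEPTANCE:
                need = 1
            else:
                need = 1 + max(
                    (depth[s.name] if s.is_internal else 0) for s in r.rhs
                )
            if need <= budget:
                viable.append(r)
        if not viable:  # unreachable when the top-level budget check passed
            raise GenerationError(
                f"no production of {symbol_name!r} fits depth budget {budget}"
            )
        r = viable[rng.integers(len(viable))]
        if r.kind == KIND_ACCEPTANCE:
            out.append(r.accepted_tokens[rng.integers(len(r.accepted_tokens))])
        else:
            for sym in r.rhs:
                if sym.is_internal:
                    expand(sym.name, budget - 1)
                else:
                    out.append(g.class_tokens(sym)[0])

    expand(g.start.name, max_depth)
    return "".join(out)


def _raw_score(s: str, g: Grammar, task: SynthTask) -> float:
    texts = [t.text for t in tokenize(s, g)]
    if task.label_rule == "contains_token":
        return float(task.param in texts)
    if task.label_rule == "substring_presence":
        return float(task.param in s)
    if task.label_rule == "token_count_threshold":
        return float(texts.count(task.param) >= task.threshold)
    if task.label_rule == "scaled_token_count":
        return float(texts.count(task.param))
    raise AssertionError(task.label_rule)


def make_dataset(task: SynthTask, g: Grammar) -> list[tuple[str, object]]:
    """Sample ``task.n`` unique labeled strings.

    Classification datasets are resampled to land the class balance inside
    ``task.balance``; regression targets are the (optionally noised) raw
    scores min-max normalized into (0.2, 0.8).  Duplicates are dropped so
    one string never carries two targets.
    """
    rng = np.random.default_rng(task.seed)
    # the minority class of a presence rule can be exponentially rare under
    # uniform rule choice, so the rejection budget is generous
    max_tries = 5000 * task.n + 1000

    if task.kind == "classification":
        lo, hi = task.balance
        want_pos = int(round(task.n * 0.5))
        want_neg = task.n - want_pos
        pos: list[str] = []
        neg: list[str] = []
        seen: set[str] = set()
        for _ in range(max_tries):
            if len(pos) >= want_pos and len(neg) >= want_neg:
                break
            s = sample_string(g, task.max_depth, rng)
            if s in seen:
                continue
            seen.add(s)
            if _raw_score(s, g, task) > 0:
                if len(pos) < want_pos:
                    pos.append(s)
            elif len(neg) < want_neg:
                neg.append(s)
        if len(pos) < want_pos or len(neg) < want_neg:
            raise GenerationError(
                f"could not draw a balanced set of {task.n} unique strings "
                f"(got {len(pos)} pos / {len(neg)} neg)"
            )
        data = [(s, POS) for s in pos] + [(s, NEG) for s in neg]
        perm = rng.permutation(len(data))
        data = [data[i] for i in perm]
        frac = sum(1 for _, y in data if y == POS) / len(data)
        assert lo <= frac <= hi
        return data

    strings: list[str] = []
    seen = set()
    for _ in range(max_tries):
        if len(strings) >= task.n:
            break
        s = sample_string(g, task.max_depth, rng)
        if s not in seen:
            seen.add(s)
            strings.append(s)
    if len(strings) < task.n:
        raise GenerationError(
            f"could not draw {task.n} unique strings within depth "
            f"{task.max_depth} (got {len(strings)})"
        )
    raw = np.array([_raw_score(s, g, task) for s in strings])
    if task.noise_sd > 0:
        raw = raw + rng.normal(0.0, task.noise_sd, size=raw.size)
    targets = normalize_targets(raw, 0.2, 0.8)
    return list(zip(strings, targets.tolist()))
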