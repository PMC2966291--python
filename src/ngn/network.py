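"""The NGN core: shared weight layers, per-molecule network assembly,
feedforward, backpropagation through structure, and training.

A *weight layer* is a weight matrix plus bias vector bound to a grammar
slot; it persists across molecules and epochs and is the unit of weight
sharing.  In the default ``per_symbol_pair`` sharing mode, layers are keyed
by (lhs symbol, child slot) of the symbol's child signature, so all
productions with the same lhs share them and slots absent from the applied
production are zero-flushed.  In ``per_rule`` mode every production carries
its own layers.  A dedicated one-unit output head sits above the start
symbol's layer; targets live in the configured output scale.

The functions in this module are the reference (object-level, numpy)
implementation; :func:`train` dispatches to a flattened numba engine
(:mod:`ngn.engine`) that performs the identical per-exemplar update, which
a test pins step-for-step against this path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import TrainingConfig
from .errors import ConfigError, DataError, LibraryMismatchError, StateError
from .grammar import Grammar, KIND_ACCEPTANCE, ProductionRule
from .parse import ParseNode, ParseTree, parse_string

OUTPUT_KEY = ("out",)


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------- #
# library layout


@dataclass(frozen=True)
class LayerSpec:
    """Shape and meaning of one library entry."""

    key: tuple
    parent_size: int
    child_size: int
    tokens: tuple[str, ...] | None = None  # set for terminal slots


def library_layout(g: Grammar, cfg: TrainingConfig) -> list[LayerSpec]:
    """Canonical ordered enumeration of weight-layer keys for a grammar.

    The order is fixed (symbols by first lhs appearance, slots by index;
    rules by index in per-rule mode; output head last) so that seeded
    initialization is reproducible.
    """
    specs: list[LayerSpec] = []
    if cfg.sharing_mode == "per_symbol_pair":
        seen: list[str] = []
        for r in g.rules:
            if r.lhs.name not in seen:
                seen.append(r.lhs.name)
        for lhs in seen:
            p = cfg.hsize(lhs)
            for slot in g.child_signature(lhs):
                if slot.is_terminal:
                    specs.append(
                        LayerSpec(("sym", lhs, slot.index), p,
                                  len(slot.accepted_tokens), slot.accepted_tokens)
                    )
                else:
                    specs.append(
                        LayerSpec(("sym", lhs, slot.index), p,
                                  cfg.hsize(slot.symbol.name))
                    )
    else:  # per_rule
        for r in g.rules:
            p = cfg.hsize(r.lhs.name)
            if r.kind == KIND_ACCEPTANCE:
                specs.append(
                    LayerSpec(("rule", r.index, 1), p,
                              len(r.accepted_tokens), r.accepted_tokens)
                )
            else:
                for pos, sym in enumerate(r.rhs):
                    if sym.is_internal:
                        specs.append(
                            LayerSpec(("rule", r.index, pos + 1), p,
                                      cfg.hsize(sym.name))
                        )
                    else:
                        toks = g.class_tokens(sym)
                        specs.append(
                            LayerSpec(("rule", r.index, pos + 1), p, len(toks), toks)
                        )
    specs.append(LayerSpec(OUTPUT_KEY, 1, cfg.hsize(g.start.name)))
    return specs


class WeightLayer:
    """Weight matrix, bias vector and their previous-step deltas (momentum)."""

    __slots__ = ("w", "b", "dw_prev", "db_prev")

    def __init__(self, w: np.ndarray, b: np.ndarray):
        self.w = np.asarray(w, dtype=float)
        self.b = np.asarray(b, dtype=float)
        if self.w.ndim != 2 or self.b.shape != (self.w.shape[0],):
            raise ConfigError(
                f"inconsistent layer shapes: w {self.w.shape}, b {self.b.shape}"
            )
        self.dw_prev = np.zeros_like(self.w)
        self.db_prev = np.zeros_like(self.b)

    @property
    def shape(self):
        return self.w.shape


class WeightLayerLibrary:
    """The persistent, finite library of shared weight layers.

    Its size depends only on the grammar and configuration, never on the
    dataset — a finite model processes inputs of unbounded length.
    """

    def __init__(self, grammar: Grammar, config: TrainingConfig,
                 layers: dict[tuple, WeightLayer], specs: list[LayerSpec]):
        self.grammar = grammar
        self.config = config
        self.layers = layers
        self.specs = {s.key: s for s in specs}
        self.key_order = [s.key for s in specs]

    @property
    def output_head(self) -> WeightLayer:
        return self.layers[OUTPUT_KEY]

    def __getitem__(self, key: tuple) -> WeightLayer:
        try:
            return self.layers[key]
        except KeyError:
            raise LibraryMismatchError(f"no weight layer for key {key!r}") from None

    def __len__(self):
        return len(self.layers)

    def copy(self) -> "WeightLayerLibrary":
        out = WeightLayerLibrary(
            self.grammar, self.config, {}, list(self.specs.values())
        )
        for k, layer in self.layers.items():
            nl = WeightLayer(layer.w.copy(), layer.b.copy())
            nl.dw_prev = layer.dw_prev.copy()
            nl.db_prev = layer.db_prev.copy()
            out.layers[k] = nl
        return out


def init_library(g: Grammar, cfg: TrainingConfig, *, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> WeightLayerLibrary:
    """Seeded two-band initialization.

    Every weight and bias entry is drawn uniformly from
    [-init_high, -init_low] u [init_low, init_high], with the band chosen
    equiprobably per entry.  The draw order follows the canonical layout,
    so the same seed yields a bit-identical library.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
    specs = library_layout(g, cfg)
    layers: dict[tuple, WeightLayer] = {}
    for spec in specs:
        def draw(shape):
            mag = rng.uniform(cfg.init_low, cfg.init_high, size=shape)
            sign = np.where(rng.random(size=shape) < 0.5, -1.0, 1.0)
            return mag * sign

        layers[spec.key] = WeightLayer(
            draw((spec.parent_size, spec.child_size)), draw((spec.parent_size,))
        )
    return WeightLayerLibrary(g, cfg, layers, specs)


def zero_library(g: Grammar, cfg: TrainingConfig) -> WeightLayerLibrary:
    """All-zero library (every hidden and output activation is then 0.5)."""
    specs = library_layout(g, cfg)
    layers = {
        s.key: WeightLayer(np.zeros((s.parent_size, s.child_size)),
                           np.zeros(s.parent_size))
        for s in specs
    }
    return WeightLayerLibrary(g, cfg, layers, specs)


# ---------------------------------------------------------------------- #
# assembly


@dataclass
class NodeLayer:
    """Activation vector of one network node, mirroring one parse node."""

    activation: np.ndarray
    kind: str  # input | hidden | output
    tree_node: ParseNode | None = None


@dataclass
class Edge:
    parent: int     # indices into AssembledNetwork.layers (topological order)
    child: int
    key: tuple


@dataclass
class AssembledNetwork:
    """Per-molecule network: node layers wired through library references.

    ``layers`` is in children-before-parents order with the start-symbol
    layer last; ``bindings`` lists every (parent, child, library-key) edge;
    ``zero_slots`` records the signature slots the applied productions left
    absent (their would-be child activation is the zero vector, so they
    contribute nothing and receive no updates).
    """

    lib: WeightLayerLibrary
    tree: ParseTree
    layers: list[NodeLayer]
    bindings: list[Edge]
    zero_slots: list[tuple[int, tuple]]
    edges_of: list[list[int]]        # per layer, indices into bindings
    output_layer: NodeLayer = None
    _ff_done: bool = False

    @property
    def root_index(self) -> int:
        return len(self.layers) - 1

    def instantiation_counts(self) -> dict[tuple, int]:
        """Occurrences of each library key in this network (incl. output head)."""
        counts: dict[tuple, int] = {}
        for e in self.bindings:
            counts[e.key] = counts.get(e.key, 0) + 1
        counts[OUTPUT_KEY] = counts.get(OUTPUT_KEY, 0) + 1
        return counts


def _slot_key(cfg: TrainingConfig, rule: ProductionRule, g: Grammar, pos: int) -> tuple:
    if cfg.sharing_mode == "per_symbol_pair":
        return ("sym", rule.lhs.name, g.slot_for(rule, pos).index)
    return ("rule", rule.index, pos + 1)


def assemble(tree: ParseTree, lib: WeightLayerLibrary) -> AssembledNetwork:
    """Build the per-molecule network for a parse tree.

    Library layers are referenced, never copied; leaf input layers are
    one-hot over the tokens their slot accepts (1.0 at the matched token,
    0.0 elsewhere).
    """
    g = lib.grammar
    cfg = lib.config
    if tree.grammar_id != g.name:
        raise LibraryMismatchError(
            f"tree parsed under {tree.grammar_id!r}, library built for {g.name!r}"
        )

    order: list[ParseNode] = []

    def post(node: ParseNode):
        for _, child in node.children:
            post(child)
        order.append(node)

    post(tree.root)
    index_of = {id(n): i for i, n in enumerate(order)}

    layers: list[NodeLayer] = [None] * len(order)
    bindings: list[Edge] = []
    edges_of: list[list[int]] = [[] for _ in order]
    zero_slots: list[tuple[int, tuple]] = []

    for i, node in enumerate(order):
        if node.is_leaf:
            continue  # leaf layers are built from their parent's slot below
        rule = node.rule
        h = cfg.hsize(node.symbol.name)
        layers[i] = NodeLayer(np.zeros(h), "hidden", node)
        occupied: set[tuple] = set()
        for pos, (slot_idx, child) in enumerate(node.children):
            key = _slot_key(cfg, rule, g, pos)
            if key not in lib.layers:
                raise LibraryMismatchError(f"no weight layer for key {key!r}")
            occupied.add(key)
            ci = index_of[id(child)]
            if child.is_leaf:
                tokens = lib.specs[key].tokens
                vec = np.zeros(len(tokens))
                vec[tokens.index(child.token.text)] = 1.0
                layers[ci] = NodeLayer(vec, "input", child)
            bindings.append(Edge(parent=i, child=ci, key=key))
            edges_of[i].append(len(bindings) - 1)
        if cfg.sharing_mode == "per_symbol_pair":
            for slot in g.child_signature(node.symbol.name):
                key = ("sym", node.symbol.name, slot.index)
                if key not in occupied:
                    zero_slots.append((i, key))

    root = layers[-1]
    net = AssembledNetwork(
        lib=lib, tree=tree, layers=layers, bindings=bindings,
        zero_slots=zero_slots, edges_of=edges_of,
        output_layer=NodeLayer(np.zeros(1), "output"),
    )
    assert root.kind in ("hidden",)
    return net


# ---------------------------------------------------------------------- #
# forward / backward / update (reference path)


def feedforward(net: AssembledNetwork) -> float:
    """Children-before-parents logistic feedforward; returns the single
    output-unit activation in (0, 1).

    Each present child slot contributes ``w @ child + b`` (one bias per
    slot layer, summed); absent slots contribute nothing.
    """
    lib = net.lib
    for i, layer in enumerate(net.layers):
        if layer.kind != "hidden":
            continue
        acc = np.zeros_like(layer.activation)
        for ei in net.edges_of[i]:
            e = net.bindings[ei]
            wl = lib[e.key]
            acc += wl.w @ net.layers[e.child].activation + wl.b
        layer.activation = logistic(acc)
    head = lib.output_head
    net.output_layer.activation = logistic(
        head.w @ net.layers[net.root_index].activation + head.b
    )
    net._ff_done = True
    return float(net.output_layer.activation[0])


@dataclass
class GradientSet:
    """Per-instantiation deltas, grouped by library key (eta folded in)."""

    per_key: dict[tuple, list[tuple[np.ndarray, np.ndarray]]] = field(default_factory=dict)
    deltas: dict[int, np.ndarray] = field(default_factory=dict)
    output_delta: float = 0.0

    def add(self, key: tuple, dw: np.ndarray, db: np.ndarray):
        self.per_key.setdefault(key, []).append((dw, db))


def backprop(net: AssembledNetwork, target: float) -> GradientSet:
    """Backpropagation through structure.

    Output delta is ``(target - out) * out * (1 - out)``; each hidden delta
    folds the logistic derivative with the parent connection; every
    occurrence of a shared key records its own delta group (their sum is
    the applied update).
    """
    if not net._ff_done:
        raise StateError("backprop called before feedforward")
    lib = net.lib
    eta = lib.config.eta
    grads = GradientSet()

    out = net.output_layer.activation
    d_out = (target - out) * out * (1.0 - out)
    grads.output_delta = float(d_out[0])
    root_act = net.layers[net.root_index].activation
    grads.add(OUTPUT_KEY, eta * np.outer(d_out, root_act), eta * d_out)

    deltas: dict[int, np.ndarray] = {}
    head = lib.output_head
    deltas[net.root_index] = root_act * (1 - root_act) * (head.w.T @ d_out)

    for i in range(len(net.layers) - 1, -1, -1):
        if net.layers[i].kind != "hidden":
            continue
        d_u = deltas[i]
        for ei in net.edges_of[i]:
            e = net.bindings[ei]
            child = net.layers[e.child]
            grads.add(e.key, eta * np.outer(d_u, child.activation), eta * d_u.copy())
            if child.kind == "hidden":
                wl = lib[e.key]
                a = child.activation
                deltas[e.child] = a * (1 - a) * (wl.w.T @ d_u)
    grads.deltas = deltas
    return grads


def apply_updates(lib: WeightLayerLibrary, grads: GradientSet,
                  cfg: TrainingConfig | None = None) -> WeightLayerLibrary:
    """Summed shared update with momentum.

    For each key: ``D = sum of instantiation deltas + alpha * D_prev``;
    ``w += D``; ``D_prev = D``.  Keys without instantiations in this
    exemplar are untouched (weights, biases and momentum buffers alike).
    """
    if cfg is None:
        cfg = lib.config
    mom = cfg.momentum_alpha
    for key, groups in grads.per_key.items():
        layer = lib[key]
        dw = sum(g[0] for g in groups)
        db = sum(g[1] for g in groups)
        if dw.shape != layer.w.shape or db.shape != layer.b.shape:
            raise LibraryMismatchError(
                f"gradient shape {dw.shape} does not match layer {layer.w.shape} "
                f"for key {key!r}"
            )
        dw = dw + mom * layer.dw_prev
        db = db + mom * layer.db_prev
        layer.w += dw
        layer.b += db
        layer.dw_prev = dw
        layer.db_prev = db
    return lib


# ---------------------------------------------------------------------- #
# training


@dataclass
class TrainingResult:
    converged: bool
    epochs: int            # epochs run in the final attempt
    restarts: int          # re-initializations used (0 = first attempt)
    final_rmse: float
    rmse_history: list[float] = field(default_factory=list)  # final attempt


def _check_targets(targets, cfg: TrainingConfig):
    t = np.asarray(targets, dtype=float)
    eps = 1e-9
    if np.any(t < cfg.output_lo - eps) or np.any(t > cfg.output_hi + eps):
        raise DataError(
            f"targets must lie within the output scale "
            f"({cfg.output_lo}, {cfg.output_hi})"
        )
    return t


def train(dataset, g: Grammar, cfg: TrainingConfig, *, seed: int | None = None,
          engine: str = "fast", trees: list[ParseTree] | None = None,
          log=None) -> tuple[WeightLayerLibrary, TrainingResult]:
    """Online (per-exemplar) training to an RMSE threshold, with restarts.

    ``dataset`` is a sequence of (string, target) pairs with targets already
    scaled into the output range.  Parse trees are computed once and cached
    across epochs; exemplar order is reshuffled every epoch from the run
    seed.  When ``max_epochs`` is exhausted the library is re-initialized
    from a derived seed, up to ``max_restarts`` times.
    """
    if seed is None:
        seed = cfg.seed
    strings = [s for s, _ in dataset]
    targets = _check_targets([t for _, t in dataset], cfg)
    if trees is None:
        trees = []
        for s in strings:
            try:
                trees.append(parse_string(s, g))
            except Exception as exc:
                raise DataError(f"exemplar {s!r} does not parse: {exc}") from exc

    n = len(trees)
    if n == 0:
        raise DataError("empty dataset")

    from . import engine as fast_engine

    flat_data = fast_engine.flatten_dataset(trees, g, cfg) if engine == "fast" else None

    lib = None
    result = None
    for attempt in range(cfg.max_restarts + 1):
        ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, attempt])
        rng = np.random.default_rng(ss)
        lib = init_library(g, cfg, rng=rng)
        history: list[float] = []
        converged = False
        epochs = 0
        if engine == "fast":
            flat_lib = fast_engine.flatten_library(lib)
            for epoch in range(cfg.max_epochs):
                order = rng.permutation(n)
                sse = fast_engine.run_epoch(flat_lib, flat_data, order, targets, cfg)
                rmse = float(np.sqrt(sse / n))
                history.append(rmse)
                epochs = epoch + 1
                if log is not None:
                    log(attempt, epoch, rmse)
                if rmse < cfg.rmse_threshold:
                    converged = True
                    break
            fast_engine.unflatten_library(flat_lib, lib)
        elif engine == "reference":
            nets = [assemble(t, lib) for t in trees]
            for epoch in range(cfg.max_epochs):
                order = rng.permutation(n)
                sse = 0.0
                for idx in order:
                    out = feedforward(nets[idx])
                    err = targets[idx] - out
                    sse += err * err
                    grads = backprop(nets[idx], targets[idx])
                    apply_updates(lib, grads, cfg)
                rmse = float(np.sqrt(sse / n))
                history.append(rmse)
                epochs = epoch + 1
                if log is not None:
                    log(attempt, epoch, rmse)
                if rmse < cfg.rmse_threshold:
                    converged = True
                    break
        else:
            raise ConfigError(f"unknown engine {engine!r}")
        result = TrainingResult(
            converged=converged, epochs=epochs, restarts=attempt,
            final_rmse=history[-1], rmse_history=history,
        )
        if converged:
            break
    return lib, result


def predict(lib: WeightLayerLibrary, s: str, g: Grammar | None = None) -> float:
    """Parse + assemble + feedforward; no state mutation."""
    if g is None:
        g = lib.grammar
    return feedforward(assemble(parse_string(s, g), lib))


def predict_many(lib: WeightLayerLibrary, strings, g: Grammar | None = None) -> np.ndarray:
    return np.array([predict(lib, s, g) for s in strings])
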