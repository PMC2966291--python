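"""Flattened numba training engine.

Trees and the weight-layer library are lowered to padded arrays once per
training run, and one jitted kernel performs a full online epoch
(feedforward, backpropagation through structure, summed shared update with
momentum, per exemplar).  The arithmetic is the same per-exemplar update as
the reference path in :mod:`ngn.network`; only the order in which the
instantiation deltas of one key are accumulated differs, which matters at
float rounding level but not beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import TrainingConfig
from .grammar import Grammar
from .network import OUTPUT_KEY, WeightLayerLibrary, _slot_key, library_layout
from .parse import ParseTree


@dataclass
class FlatLibrary:
    keys: list[tuple]
    kid: dict[tuple, int]
    psz: np.ndarray
    csz: np.ndarray
    W: np.ndarray        # (K, Pmax, Cmax), padded with zeros
    B: np.ndarray        # (K, Pmax)
    DW: np.ndarray
    DB: np.ndarray
    out_kid: int


@dataclass
class FlatDataset:
    n_off: np.ndarray    # per tree, offset into node arrays
    n_cnt: np.ndarray
    nsz: np.ndarray      # per node, activation-vector length
    hot: np.ndarray      # per node, one-hot index (leaves) or -1
    nes: np.ndarray      # per node, first edge index
    nee: np.ndarray      # per node, one past last edge index
    ekey: np.ndarray     # per edge, library key id
    echild: np.ndarray   # per edge, child index local to the tree
    max_nodes: int
    amax: int            # widest activation vector
    pmax: int


def flatten_library(lib: WeightLayerLibrary) -> FlatLibrary:
    keys = list(lib.key_order)
    kid = {k: i for i, k in enumerate(keys)}
    psz = np.array([lib.specs[k].parent_size for k in keys], dtype=np.int64)
    csz = np.array([lib.specs[k].child_size for k in keys], dtype=np.int64)
    pmax, cmax = int(psz.max()), int(csz.max())
    K = len(keys)
    W = np.zeros((K, pmax, cmax))
    B = np.zeros((K, pmax))
    DW = np.zeros_like(W)
    DB = np.zeros_like(B)
    for i, k in enumerate(keys):
        layer = lib.layers[k]
        p, c = layer.w.shape
        W[i, :p, :c] = layer.w
        B[i, :p] = layer.b
        DW[i, :p, :c] = layer.dw_prev
        DB[i, :p] = layer.db_prev
    return FlatLibrary(keys, kid, psz, csz, W, B, DW, DB, kid[OUTPUT_KEY])


def unflatten_library(flat: FlatLibrary, lib: WeightLayerLibrary) -> None:
    """Write trained values back into the object library."""
    for i, k in enumerate(flat.keys):
        layer = lib.layers[k]
        p, c = layer.w.shape
        layer.w[...] = flat.W[i, :p, :c]
        layer.b[...] = flat.B[i, :p]
        layer.dw_prev[...] = flat.DW[i, :p, :c]
        layer.db_prev[...] = flat.DB[i, :p]


def flatten_dataset(trees: list[ParseTree], g: Grammar,
                    cfg: TrainingConfig) -> FlatDataset:
    specs = {s.key: s for s in library_layout(g, cfg)}
    kid = {k: i for i, k in enumerate(specs)}

    n_off, n_cnt = [], []
    nsz, hot, nes, nee = [], [], [], []
    ekey, echild = [], []

    for tree in trees:
        order = []

        def post(node):
            for _, child in node.children:
                post(child)
            order.append(node)

        post(tree.root)
        index_of = {id(n): i for i, n in enumerate(order)}
        n_off.append(len(nsz))
        n_cnt.append(len(order))

        # sizes/hot set when a parent wires its leaf children
        local_sz = [0] * len(order)
        local_hot = [-1] * len(order)
        local_edges: list[list[tuple[int, int]]] = [[] for _ in order]
        for i, node in enumerate(order):
            if node.is_leaf:
                continue
            local_sz[i] = cfg.hsize(node.symbol.name)
            for pos, (_, child) in enumerate(node.children):
                key = _slot_key(cfg, node.rule, g, pos)
                ci = index_of[id(child)]
                if child.is_leaf:
                    tokens = specs[key].tokens
                    local_sz[ci] = len(tokens)
                    local_hot[ci] = tokens.index(child.token.text)
                local_edges[i].append((kid[key], ci))
        for i in range(len(order)):
            nsz.append(local_sz[i])
            hot.append(local_hot[i])
            nes.append(len(ekey))
            for k, c in local_edges[i]:
                ekey.append(k)
                echild.append(c)
            nee.append(len(ekey))

    psz = np.array([s.parent_size for s in specs.values()], dtype=np.int64)
    return FlatDataset(
        n_off=np.array(n_off, dtype=np.int64),
        n_cnt=np.array(n_cnt, dtype=np.int64),
        nsz=np.array(nsz, dtype=np.int64),
        hot=np.array(hot, dtype=np.int64),
        nes=np.array(nes, dtype=np.int64),
        nee=np.array(nee, dtype=np.int64),
        ekey=np.array(ekey, dtype=np.int64),
        echild=np.array(echild, dtype=np.int64),
        max_nodes=int(max(n_cnt)),
        amax=int(max(nsz)),
        pmax=int(psz.max()),
    )


@njit(cache=True)
def _epoch_kernel(order, targets, W, B, DW, DB, psz, csz,
                  n_off, n_cnt, nsz, hot, nes, nee, ekey, echild,
                  outk, eta, mom, act, dlt, netbuf, gW, gB, used, usedlist):
    sse = 0.0
    for oi in range(order.shape[0]):
        ex = order[oi]
        base = n_off[ex]
        nn = n_cnt[ex]
        # ---- feedforward (children before parents) ----
        for i in range(nn):
            gidx = base + i
            sz = nsz[gidx]
            if hot[gidx] >= 0:
                for j in range(sz):
                    act[i, j] = 0.0
                act[i, hot[gidx]] = 1.0
            else:
                for j in range(sz):
                    netbuf[j] = 0.0
                for e in range(nes[gidx], nee[gidx]):
                    k = ekey[e]
                    c = echild[e]
                    p = psz[k]
                    cc = csz[k]
                    for j in range(p):
                        s = B[k, j]
                        for m in range(cc):
                            s += W[k, j, m] * act[c, m]
                        netbuf[j] += s
                for j in range(sz):
                    act[i, j] = 1.0 / (1.0 + np.exp(-netbuf[j]))
        root = nn - 1
        h = nsz[base + root]
        s = B[outk, 0]
        for m in range(h):
            s += W[outk, 0, m] * act[root, m]
        out = 1.0 / (1.0 + np.exp(-s))
        err = targets[ex] - out
        sse += err * err
        # ---- backprop through structure ----
        nused = 0
        dout = err * out * (1.0 - out)
        used[outk] = 1
        usedlist[nused] = outk
        nused += 1
        for m in range(h):
            gW[outk, 0, m] += eta * dout * act[root, m]
        gB[outk, 0] += eta * dout
        for j in range(h):
            a = act[root, j]
            dlt[root, j] = a * (1.0 - a) * W[outk, 0, j] * dout
        for i in range(nn - 1, -1, -1):
            gidx = base + i
            if hot[gidx] >= 0:
                continue
            for e in range(nes[gidx], nee[gidx]):
                k = ekey[e]
                c = echild[e]
                p = psz[k]
                cc = csz[k]
                if used[k] == 0:
                    used[k] = 1
                    usedlist[nused] = k
                    nused += 1
                for j in range(p):
                    d = eta * dlt[i, j]
                    gB[k, j] += d
                    for m in range(cc):
                        gW[k, j, m] += d * act[c, m]
                if hot[base + c] < 0:
                    for m in range(cc):
                        s2 = 0.0
                        for j in range(p):
                            s2 += W[k, j, m] * dlt[i, j]
                        a = act[c, m]
                        dlt[c, m] = a * (1.0 - a) * s2
        # ---- summed shared update with momentum ----
        for ui in range(nused):
            k = usedlist[ui]
            used[k] = 0
            p = psz[k]
            cc = csz[k]
            for j in range(p):
                db = gB[k, j] + mom * DB[k, j]
                B[k, j] += db
                DB[k, j] = db
                gB[k, j] = 0.0
                for m in range(cc):
                    dw = gW[k, j, m] + mom * DW[k, j, m]
                    W[k, j, m] += dw
                    DW[k, j, m] = dw
                    gW[k, j, m] = 0.0
    return sse


def run_epoch(flat: FlatLibrary, data: FlatDataset, order: np.ndarray,
              targets: np.ndarray, cfg: TrainingConfig) -> float:
    """One online epoch over ``order``; returns the sum of squared errors."""
    K, pmax, cmax = flat.W.shape
    act = np.zeros((data.max_nodes, max(data.amax, 1)))
    dlt = np.zeros_like(act)
    netbuf = np.zeros(max(pmax, data.amax, 1))
    gW = np.zeros_like(flat.W)
    gB = np.zeros_like(flat.B)
    used = np.zeros(K, dtype=np.int64)
    usedlist = np.zeros(K, dtype=np.int64)
    return float(
        _epoch_kernel(
            np.asarray(order, dtype=np.int64), np.asarray(targets, dtype=float),
            flat.W, flat.B, flat.DW, flat.DB, flat.psz, flat.csz,
            data.n_off, data.n_cnt, data.nsz, data.hot,
            data.nes, data.nee, data.ekey, data.echild,
            flat.out_kid, float(cfg.eta), float(cfg.momentum_alpha),
            act, dlt, netbuf, gW, gB, used, usedlist,
        )
    )
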