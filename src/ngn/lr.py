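"""Canonical LR(1) table construction.

The determinism requirement on NGN grammars is operationalised here: a
grammar is accepted when its LR(1) ACTION table is conflict-free (canonical
LR(1) accepts a superset of the LALR(1) grammars, so every LALR(1)-clean
grammar passes).  Because several terminal classes may admit the same token
text (``'-'`` is a bond symbol and a charge sign), construction additionally
checks that no parser state can shift two different classes for one text —
otherwise the lexer's class dispatch would be ambiguous.

Production right-hand sides are never empty in this rule format, which
removes nullable-symbol bookkeeping from FIRST sets and closures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .grammar import ConflictReport, Grammar, KIND_ACCEPTANCE

EOF = "$end"
_ACCEPT_PID = 0  # augmented production $accept -> start


@dataclass
class ParseTables:
    """ACTION/GOTO tables plus the conflict report.

    ``action[state][terminal]`` is ``("shift", j)``, ``("reduce", rule_index)``
    or ``("accept",)``; ``goto[state][nonterminal]`` is a state id.  Conflicts
    are resolved (shift preferred, then lowest rule index) so that parsing
    with ``allow_conflicts`` grammars remains well-defined.
    """

    action: list[dict[str, tuple]]
    goto: list[dict[str, int]]
    report: ConflictReport
    rhs_len: dict[int, int] = field(default_factory=dict)
    lhs_name: dict[int, str] = field(default_factory=dict)


def build_tables(g: Grammar) -> ParseTables:
    # productions: pid 0 is the augmented start; pid i>0 is grammar rule i.
    prods: dict[int, tuple[str, tuple[str, ...]]] = {
        _ACCEPT_PID: ("$accept", (g.start.name,))
    }
    for r in g.rules:
        prods[r.index] = (r.lhs.name, tuple(s.name for s in r.rhs))

    nonterminals = set(g.internal_symbols) | {"$accept"}
    by_lhs: dict[str, list[int]] = {}
    for pid, (lhs, _) in prods.items():
        by_lhs.setdefault(lhs, []).append(pid)
    for lhs in by_lhs:
        by_lhs[lhs].sort()

    # FIRST sets (no epsilon productions in this format)
    first: dict[str, frozenset[str]] = {}
    for name in nonterminals:
        first[name] = frozenset()
    changed = True
    while changed:
        changed = False
        for pid, (lhs, rhs) in prods.items():
            head = rhs[0]
            add = first[head] if head in nonterminals else frozenset([head])
            if not add <= first[lhs]:
                first[lhs] = first[lhs] | add
                changed = True

    def first_of(sym: str) -> frozenset[str]:
        return first[sym] if sym in nonterminals else frozenset([sym])

    # LR(1) items: (pid, dot, lookahead)
    def closure(items: frozenset[tuple[int, int, str]]) -> frozenset:
        out = set(items)
        stack = list(items)
        while stack:
            pid, dot, la = stack.pop()
            _, rhs = prods[pid]
            if dot >= len(rhs):
                continue
            nxt = rhs[dot]
            if nxt not in nonterminals:
                continue
            lookaheads = first_of(rhs[dot + 1]) if dot + 1 < len(rhs) else frozenset([la])
            for p2 in by_lhs.get(nxt, ()):
                for la2 in lookaheads:
                    item = (p2, 0, la2)
                    if item not in out:
                        out.add(item)
                        stack.append(item)
        return frozenset(out)

    start_state = closure(frozenset({(_ACCEPT_PID, 0, EOF)}))
    states: dict[frozenset, int] = {start_state: 0}
    order: list[frozenset] = [start_state]
    transitions: dict[tuple[int, str], int] = {}
    i = 0
    while i < len(order):
        st = order[i]
        by_sym: dict[str, set] = {}
        for pid, dot, la in st:
            _, rhs = prods[pid]
            if dot < len(rhs):
                by_sym.setdefault(rhs[dot], set()).add((pid, dot + 1, la))
        for sym, kernel in sorted(by_sym.items()):
            nxt = closure(frozenset(kernel))
            if nxt not in states:
                states[nxt] = len(order)
                order.append(nxt)
            transitions[(i, sym)] = states[nxt]
        i += 1

    n = len(order)
    action: list[dict[str, tuple]] = [dict() for _ in range(n)]
    goto: list[dict[str, int]] = [dict() for _ in range(n)]
    conflicts: list[tuple[str, tuple[str, ...]]] = []

    def describe(act: tuple) -> str:
        if act[0] == "shift":
            return f"shift to state {act[1]}"
        if act[0] == "reduce":
            return f"reduce by rule {act[1]}"
        return "accept"

    def put(state: int, term: str, act: tuple):
        cur = action[state].get(term)
        if cur is None:
            action[state][term] = act
            return
        if cur == act:
            return
        kind = (
            "shift/reduce"
            if {"shift", "reduce"} == {cur[0], act[0]}
            else f"{cur[0]}/{act[0]}"
        )
        conflicts.append(
            (
                f"state {state}, lookahead {term!r} ({kind})",
                (describe(cur), describe(act)),
            )
        )
        # resolution for allow-conflicts mode: shift wins, then lowest rule
        if cur[0] == "shift" or act[0] == "shift":
            keep = cur if cur[0] == "shift" else act
        else:
            keep = cur if cur[1] <= act[1] else act
        action[state][term] = keep

    for (state, sym), dest in sorted(transitions.items()):
        if sym in nonterminals:
            goto[state][sym] = dest
        else:
            put(state, sym, ("shift", dest))
    for st in order:
        sid = states[st]
        for pid, dot, la in sorted(st):
            _, rhs = prods[pid]
            if dot == len(rhs):
                if pid == _ACCEPT_PID:
                    put(sid, EOF, ("accept",))
                else:
                    put(sid, la, ("reduce", pid))

    # token-dispatch check: one text, two shiftable classes in the same state
    text_multi = {t: cs for t in g.token_texts if len(cs := g.classes_for_text(t)) > 1}
    for sid in range(n):
        for text, classes in text_multi.items():
            live = [c for c in classes if c in action[sid]]
            if len(live) > 1:
                conflicts.append(
                    (
                        f"state {sid}, token text {text!r} (token-dispatch)",
                        tuple(f"class {c}" for c in live),
                    )
                )

    report = ConflictReport(conflicts=conflicts, n_states=n)
    tables = ParseTables(action=action, goto=goto, report=report)
    for r in g.rules:
        tables.rhs_len[r.index] = 1 if r.kind == KIND_ACCEPTANCE else len(r.rhs)
        tables.lhs_name[r.index] = r.lhs.name
    return tables
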