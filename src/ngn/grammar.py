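"""Deterministic context-free grammars for molecular line notations.

A grammar is the four-tuple <V, Sigma, s, P>: internal symbols, terminal
token classes, a start symbol and an ordered list of production rules.
Two kinds of rule are distinguished:

* *expansion* rules rewrite an internal symbol into a sequence of symbols
  (mostly internal; a quoted literal such as ``'('`` is allowed inline and
  becomes a single-token terminal-class slot);
* *acceptance* rules rewrite an internal symbol into a single terminal
  class that admits one or more concrete tokens (``atom <- 'C'``,
  ``digit <- '0' '1' ... '9'``).

Rule indices are 1-based in file order; they double as the identifiers of
the shared weight layers in the per-rule sharing mode of the network, and
as the entries of leftmost derivations.

Grammar-file format: one rule per line, ``lhs <- item item ...`` where a
bare name is an internal symbol and a single-quoted string is a token.
``#`` starts a comment outside quotes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import (
    GrammarReferenceError,
    GrammarSyntaxError,
    GrammarValidationError,
    NondeterministicGrammarError,
)

ROLE_INTERNAL = "internal"
ROLE_TERMINAL = "terminal-class"

KIND_EXPANSION = "expansion"
KIND_ACCEPTANCE = "acceptance"

BUILTIN_NAMES = ("smiles_subset", "smiles_extended", "inchi_basic")


@dataclass(frozen=True)
class Symbol:
    """A grammar symbol: an internal symbol of V or a terminal class of Sigma."""

    name: str
    role: str = ROLE_INTERNAL

    @property
    def is_internal(self) -> bool:
        return self.role == ROLE_INTERNAL

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


@dataclass(frozen=True)
class ProductionRule:
    """One production ``lhs <- rhs``, indexed 1..|P| in declaration order.

    For acceptance rules ``rhs`` is a single terminal-class symbol and
    ``accepted_tokens`` lists the concrete token strings it admits.
    """

    index: int
    lhs: Symbol
    rhs: tuple[Symbol, ...]
    kind: str
    accepted_tokens: tuple[str, ...] = ()

    def __post_init__(self):
        if self.index < 1:
            raise GrammarValidationError(f"rule index must be positive, got {self.index}")
        if not self.lhs.is_internal:
            raise GrammarValidationError(f"rule {self.index}: lhs must be internal")
        if not self.rhs:
            raise GrammarValidationError(f"rule {self.index}: empty right-hand side")
        if self.kind == KIND_ACCEPTANCE:
            if len(self.rhs) != 1 or self.rhs[0].is_internal:
                raise GrammarValidationError(
                    f"rule {self.index}: acceptance rhs must be a single terminal class"
                )
            if not self.accepted_tokens:
                raise GrammarValidationError(f"rule {self.index}: no accepted tokens")
            if len(set(self.accepted_tokens)) != len(self.accepted_tokens):
                raise GrammarValidationError(
                    f"rule {self.index}: duplicate accepted tokens"
                )
        elif self.kind == KIND_EXPANSION:
            if self.accepted_tokens:
                raise GrammarValidationError(
                    f"rule {self.index}: expansion rules carry no accepted_tokens"
                )
        else:
            raise GrammarValidationError(f"rule {self.index}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class Slot:
    """One child slot of an internal symbol's signature (1-based index).

    ``accepted_tokens`` is set for terminal slots; for the merged acceptance
    slot of an lhs it is the union of that lhs's acceptance rules' tokens in
    rule-index order.
    """

    symbol: Symbol
    index: int
    accepted_tokens: tuple[str, ...] | None = None

    @property
    def is_terminal(self) -> bool:
        return self.accepted_tokens is not None


@dataclass
class ConflictReport:
    """LR-determinism report: shift/reduce, reduce/reduce and token-dispatch
    conflicts found while building the parse tables."""

    conflicts: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    n_states: int = 0

    @property
    def is_deterministic(self) -> bool:
        return not self.conflicts

    def __str__(self) -> str:
        if self.is_deterministic:
            return f"deterministic ({self.n_states} LR states, no conflicts)"
        lines = [f"{len(self.conflicts)} conflict(s) in {self.n_states} LR states:"]
        for state, actions in self.conflicts:
            lines.append(f"  {state}: " + " vs ".join(actions))
        return "\n".join(lines)


class Grammar:
    """An ordered, validated rule set over declared symbols.

    Construction validates the structural invariants (start symbol internal,
    every referenced symbol declared, indices 1..|P| unique). The LR
    determinism check is separate (:func:`validate_deterministic`) because
    conflicts are data, not errors.
    """

    def __init__(self, name: str, rules: list[ProductionRule], start: Symbol):
        self.name = name
        self.rules: tuple[ProductionRule, ...] = tuple(rules)
        self.start = start
        indices = [r.index for r in self.rules]
        if sorted(indices) != list(range(1, len(self.rules) + 1)):
            raise GrammarValidationError(
                f"rule indices must be exactly 1..{len(self.rules)}, got {indices}"
            )
        if len(set(indices)) != len(indices):
            raise GrammarValidationError("duplicate rule index")

        internals: dict[str, Symbol] = {}
        terminals: dict[str, Symbol] = {}
        for r in self.rules:
            internals.setdefault(r.lhs.name, r.lhs)
        if not start.is_internal or start.name not in internals:
            raise GrammarValidationError(f"start symbol {start.name!r} is not internal")

        # class_tokens: terminal-class name -> token texts it admits
        self._class_tokens: dict[str, tuple[str, ...]] = {}
        for r in self.rules:
            for sym in r.rhs:
                if sym.is_internal:
                    if sym.name not in internals:
                        raise GrammarReferenceError(
                            f"rule {r.index}: undeclared symbol {sym.name!r}"
                        )
                else:
                    terminals.setdefault(sym.name, sym)
            if r.kind == KIND_ACCEPTANCE:
                self._class_tokens[r.rhs[0].name] = r.accepted_tokens
        for r in self.rules:
            if r.kind == KIND_EXPANSION:
                for sym in r.rhs:
                    if not sym.is_internal and sym.name not in self._class_tokens:
                        # inline literal class, named "'tok'"
                        self._class_tokens[sym.name] = (sym.name[1:-1],)

        self.internal_symbols: dict[str, Symbol] = internals
        self.terminal_classes: dict[str, Symbol] = terminals

        # token text -> terminal-class names that admit it (declaration order)
        self._text_classes: dict[str, list[str]] = {}
        for r in self.rules:
            for sym in r.rhs:
                if not sym.is_internal:
                    for tok in self._class_tokens[sym.name]:
                        lst = self._text_classes.setdefault(tok, [])
                        if sym.name not in lst:
                            lst.append(sym.name)

        # rules grouped by lhs, in index order
        self._rules_by_lhs: dict[str, list[ProductionRule]] = {}
        for r in self.rules:
            self._rules_by_lhs.setdefault(r.lhs.name, []).append(r)

        self._signatures: dict[str, tuple[Slot, ...]] = {}
        self._slot_of_pos: dict[tuple[int, int], int] = {}
        self._build_signatures()
        self._tables = None  # lazy LR tables (see ngn.lr)

    # ------------------------------------------------------------------ #

    def _build_signatures(self):
        """Per-symbol child signatures: the union over an lhs's productions of
        right-hand slots, ordered by first appearance by rule index.

        All acceptance rules of an lhs merge into a single terminal slot whose
        tokens are the concatenation of their accepted_tokens in rule order;
        inline literal terminals in expansions get their own single-token
        slots keyed by class and occurrence.
        """
        for lhs_name, rules in self._rules_by_lhs.items():
            order: list[tuple] = []  # slot keys in first-appearance order
            keymap: dict[tuple, int] = {}
            merged_tokens: list[str] = []
            for r in rules:
                if r.kind == KIND_ACCEPTANCE:
                    key = ("#tokens",)
                    if key not in keymap:
                        keymap[key] = len(order)
                        order.append(key)
                    self._slot_of_pos[(r.index, 0)] = keymap[key]
                    merged_tokens.extend(r.accepted_tokens)
                else:
                    occ: dict[str, int] = {}
                    for pos, sym in enumerate(r.rhs):
                        k = occ.get(sym.name, 0)
                        occ[sym.name] = k + 1
                        key = (sym.name, k)
                        if key not in keymap:
                            keymap[key] = len(order)
                            order.append(key)
                        self._slot_of_pos[(r.index, pos)] = keymap[key]
            if len(set(merged_tokens)) != len(merged_tokens):
                raise GrammarValidationError(
                    f"acceptance rules for {lhs_name!r} admit overlapping tokens"
                )
            slots = []
            for i, key in enumerate(order):
                if key == ("#tokens",):
                    sym = Symbol(f"{lhs_name}[tok]", ROLE_TERMINAL)
                    slots.append(Slot(sym, i + 1, tuple(merged_tokens)))
                else:
                    name, _ = key
                    if name in self.internal_symbols:
                        slots.append(Slot(self.internal_symbols[name], i + 1))
                    else:
                        sym = self.terminal_classes[name]
                        slots.append(Slot(sym, i + 1, self._class_tokens[name]))
            self._signatures[lhs_name] = tuple(slots)

    # ------------------------------------------------------------------ #

    def rules_for(self, lhs: str | Symbol) -> list[ProductionRule]:
        name = lhs.name if isinstance(lhs, Symbol) else lhs
        return list(self._rules_by_lhs.get(name, []))

    def class_tokens(self, terminal_class: str | Symbol) -> tuple[str, ...]:
        name = terminal_class.name if isinstance(terminal_class, Symbol) else terminal_class
        return self._class_tokens[name]

    def classes_for_text(self, text: str) -> tuple[str, ...]:
        """Terminal classes whose token set contains this exact text."""
        return tuple(self._text_classes.get(text, ()))

    @property
    def token_texts(self) -> tuple[str, ...]:
        return tuple(self._text_classes)

    def child_signature(self, lhs: str | Symbol) -> tuple[Slot, ...]:
        name = lhs.name if isinstance(lhs, Symbol) else lhs
        if name not in self.internal_symbols:
            raise GrammarValidationError(f"{name!r} is not an internal symbol")
        return self._signatures[name]

    def slot_for(self, rule: ProductionRule, pos: int) -> Slot:
        """The signature slot that position ``pos`` of ``rule``'s rhs occupies."""
        return self._signatures[rule.lhs.name][self._slot_of_pos[(rule.index, pos)]]

    # ------------------------------------------------------------------ #

    def tables(self):
        """Lazily built LR(1) parse tables (shared with the parser)."""
        if self._tables is None:
            from .lr import build_tables

            self._tables = build_tables(self)
        return self._tables

    def serialize(self) -> str:
        """Grammar-file text that :func:`load_grammar` reads back identically."""
        lines = [f"# grammar: {self.name}"]
        for r in self.rules:
            if r.kind == KIND_ACCEPTANCE:
                rhs = " ".join(f"'{t}'" for t in r.accepted_tokens)
            else:
                parts = []
                for sym in r.rhs:
                    if sym.is_internal:
                        parts.append(sym.name)
                    else:
                        parts.append(f"'{self._class_tokens[sym.name][0]}'")
                rhs = " ".join(parts)
            lines.append(f"{r.lhs.name} <- {rhs}")
        return "\n".join(lines) + "\n"

    def __repr__(self) -> str:
        return (
            f"<Grammar {self.name!r}: {len(self.rules)} rules, "
            f"start={self.start.name!r}>"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Grammar):
            return NotImplemented
        return (
            self.start == other.start
            and self.rules == other.rules
        )

    __hash__ = None


# ---------------------------------------------------------------------- #
# loading

_ITEM_RE = re.compile(r"'[^']*'|\S+")


def _split_items(line: str) -> list[str]:
    """Split a rule line into quoted/bare items, dropping unquoted comments."""
    items = []
    for m in _ITEM_RE.finditer(line):
        it = m.group(0)
        if not it.startswith("'") and it.startswith("#"):
            break
        items.append(it)
    return items


def load_grammar(text: str, *, name: str = "user", allow_conflicts: bool = False) -> Grammar:
    """Parse grammar-file content into a validated :class:`Grammar`.

    Determinism is enforced at load: grammars whose LR(1) tables contain
    conflicts raise :class:`NondeterministicGrammarError` unless
    ``allow_conflicts`` is set, in which case parsing later resolves ties by
    preferring shifts and the first-listed rule.
    """
    raw_rules: list[tuple[int, str, list[str]]] = []  # (line_no, lhs, rhs items)
    for line_no, line in enumerate(text.splitlines(), start=1):
        items = _split_items(line)
        if not items:
            continue
        if len(items) < 3 or items[1] != "<-" or items[0].startswith("'"):
            raise GrammarSyntaxError(
                f"expected \"lhs <- item ...\", got {line.strip()!r}", line=line_no
            )
        raw_rules.append((line_no, items[0], items[2:]))
    if not raw_rules:
        raise GrammarSyntaxError("grammar file declares no rules")

    internal_names = {lhs for _, lhs, _ in raw_rules}
    internals = {n: Symbol(n, ROLE_INTERNAL) for n in internal_names}

    # terminal-class naming: acceptance classes take the token text when the
    # rule admits one token and "<lhs>.tokens" otherwise; inline literals take
    # the quoted form "'tok'".  Collisions append the rule index.
    taken: set[str] = set(internal_names)
    rules: list[ProductionRule] = []
    for idx, (line_no, lhs, items) in enumerate(raw_rules, start=1):
        quoted = [it.startswith("'") for it in items]
        if all(quoted):
            tokens = tuple(it[1:-1] for it in items)
            if any(not t for t in tokens):
                raise GrammarSyntaxError("empty token literal", line=line_no)
            if len(set(tokens)) != len(tokens):
                raise GrammarSyntaxError("duplicate token in acceptance rule", line=line_no)
            base = tokens[0] if len(tokens) == 1 else f"{lhs}.tokens"
            cname = base if base not in taken else f"{base}@{idx}"
            taken.add(cname)
            rules.append(
                ProductionRule(
                    index=idx,
                    lhs=internals[lhs],
                    rhs=(Symbol(cname, ROLE_TERMINAL),),
                    kind=KIND_ACCEPTANCE,
                    accepted_tokens=tokens,
                )
            )
        else:
            rhs: list[Symbol] = []
            for it in items:
                if it.startswith("'"):
                    tok = it[1:-1]
                    if not tok:
                        raise GrammarSyntaxError("empty token literal", line=line_no)
                    rhs.append(Symbol(f"'{tok}'", ROLE_TERMINAL))
                else:
                    if it not in internals:
                        raise GrammarReferenceError(
                            f"line {line_no}: undeclared symbol {it!r} "
                            "(bare names must appear as a rule's left-hand side)"
                        )
                    rhs.append(internals[it])
            rules.append(
                ProductionRule(
                    index=idx, lhs=internals[lhs], rhs=tuple(rhs), kind=KIND_EXPANSION
                )
            )

    g = Grammar(name=name, rules=rules, start=rules[0].lhs)
    report = validate_deterministic(g)
    if not report.is_deterministic:
        if not allow_conflicts:
            raise NondeterministicGrammarError(str(report))
        import warnings

        warnings.warn(
            f"grammar {name!r} has LR conflicts; parsing will prefer shifts and "
            f"first-listed rules.\n{report}",
            stacklevel=2,
        )
    return g


def validate_deterministic(g: Grammar) -> ConflictReport:
    """Build LR(1) parse tables and report every conflict found."""
    return g.tables().report


def child_signature(g: Grammar, lhs: str | Symbol) -> tuple[Slot, ...]:
    """Ordered child slots of an internal symbol (see :meth:`Grammar.child_signature`)."""
    return g.child_signature(lhs)


# ---------------------------------------------------------------------- #
# built-ins

_BUILTIN_CACHE: dict[str, Grammar] = {}


def builtin_grammar(name: str) -> Grammar:
    """One of the shipped grammars: ``smiles_subset`` (the 10-rule teaching
    fragment), ``smiles_extended`` (organic-subset SMILES with bonds, rings
    and bracket atoms) or ``inchi_basic`` (InChI header, formula, /c and /h
    layers as opaque token sequences)."""
    if name not in BUILTIN_NAMES:
        raise LookupError(f"unknown builtin grammar {name!r}; available: {BUILTIN_NAMES}")
    if name not in _BUILTIN_CACHE:
        from importlib.resources import files

        text = files("ngn").joinpath("grammars", f"{name}.grammar").read_text()
        _BUILTIN_CACHE[name] = load_grammar(text, name=name)
    return _BUILTIN_CACHE[name]
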