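"""Tokenization and deterministic parsing of molecular strings.

The tokenizer is a greedy longest-match scanner over the union of every
token the grammar accepts (needed so that ``Cl``/``Br`` beat ``C``/``B``).
The parser is a table-driven LR(1) shift-reduce automaton; for an
unambiguous grammar the resulting :class:`ParseTree` is the unique
structural interpretation of the string, and parsing the same string twice
yields identical trees.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ParseError, TokenizationError
from .grammar import Grammar, ProductionRule, Symbol
from .lr import EOF


@dataclass(frozen=True)
class Token:
    """One lexeme: its text, terminal class and 0-based character offset.

    When a text is admitted by several terminal classes, ``terminal_class``
    is the first-declared candidate and ``candidates`` carries all of them;
    the parser resolves the class from its state.
    """

    text: str
    terminal_class: Symbol
    position: int
    candidates: tuple[str, ...] = ()


@dataclass
class ParseNode:
    """A node of the parse tree.

    Internal nodes carry the production rule applied at that point and an
    ordered list of ``(slot_index, child)`` pairs, where the slot index is
    the child's position in the lhs symbol's child signature (1-based).
    Leaves carry the matched token and no rule.
    """

    id: int
    symbol: Symbol
    rule: ProductionRule | None = None
    children: list[tuple[int, "ParseNode"]] = field(default_factory=list)
    token: Token | None = None

    @property
    def is_leaf(self) -> bool:
        return self.token is not None


@dataclass
class ParseTree:
    """The rooted, directed, acyclic derivation structure of one string."""

    root: ParseNode
    source: str
    grammar_id: str

    def walk(self):
        """Pre-order (leftmost, depth-first) traversal of all nodes."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for _, child in reversed(node.children):
                stack.append(child)

    def internal_nodes(self):
        return [n for n in self.walk() if not n.is_leaf]

    def leaves(self):
        return [n for n in self.walk() if n.is_leaf]

    def leftmost_derivation(self) -> list[int]:
        """Rule indices in pre-order: the leftmost derivation of the source."""
        return [n.rule.index for n in self.internal_nodes()]

    def rule_usage_counts(self) -> dict[int, int]:
        """How many times each production (hence each per-rule weight layer)
        is instantiated in this tree."""
        return dict(Counter(self.leftmost_derivation()))


def tokenize(s: str, g: Grammar) -> list[Token]:
    """Greedy longest-match scan of ``s`` over the grammar's token union."""
    if not s:
        raise TokenizationError("empty input string", offset=0)
    texts = sorted(g.token_texts, key=len, reverse=True)
    tokens: list[Token] = []
    pos = 0
    while pos < len(s):
        for text in texts:
            if s.startswith(text, pos):
                classes = g.classes_for_text(text)
                sym = g.terminal_classes[classes[0]]
                tokens.append(Token(text, sym, pos, candidates=classes))
                pos += len(text)
                break
        else:
            raise TokenizationError(f"unrecognized character {s[pos]!r}", offset=pos)
    return tokens


def parse(tokens: list[Token], g: Grammar) -> ParseTree:
    """Shift-reduce parse of a token sequence into its unique tree."""
    tables = g.tables()
    rule_by_index = {r.index: r for r in g.rules}

    state_stack = [0]
    node_stack: list[ParseNode] = []
    next_id = 0

    def fresh_id() -> int:
        nonlocal next_id
        next_id += 1
        return next_id - 1

    def resolve(tok: Token | None) -> str:
        """Pick the terminal class of a token given the current LR state."""
        if tok is None:
            return EOF
        live = [c for c in tok.candidates if c in tables.action[state_stack[-1]]]
        if len(live) == 1:
            return live[0]
        if not live:
            return tok.candidates[0]  # will yield a syntax error below
        raise ParseError(
            f"ambiguous terminal class for token {tok.text!r} at position "
            f"{tok.position}: {live}",
            position=tok.position,
        )

    stream = list(tokens) + [None]
    i = 0
    while True:
        tok = stream[i]
        term = resolve(tok)
        act = tables.action[state_stack[-1]].get(term)
        if act is None:
            if tok is None:
                raise ParseError("unexpected end of input", position=len(tokens))
            raise ParseError(
                f"unexpected token {tok.text!r} at position {tok.position}",
                position=tok.position,
            )
        if act[0] == "shift":
            sym = g.terminal_classes[term]
            node_stack.append(
                ParseNode(
                    id=fresh_id(),
                    symbol=sym,
                    token=Token(tok.text, sym, tok.position, tok.candidates),
                )
            )
            state_stack.append(act[1])
            i += 1
        elif act[0] == "reduce":
            rule = rule_by_index[act[1]]
            k = tables.rhs_len[rule.index]
            children = node_stack[-k:]
            del node_stack[-k:]
            del state_stack[-k:]
            node = ParseNode(id=fresh_id(), symbol=rule.lhs, rule=rule)
            node.children = [
                (g.slot_for(rule, pos).index, child)
                for pos, child in enumerate(children)
            ]
            node_stack.append(node)
            state_stack.append(tables.goto[state_stack[-1]][rule.lhs.name])
        else:  # accept
            break

    root = node_stack[0]
    # renumber ids in pre-order so identical strings get identical trees
    tree = ParseTree(
        root=root,
        source="".join(t.text for t in tokens),
        grammar_id=g.name,
    )
    for i, node in enumerate(tree.walk()):
        node.id = i
    return tree


def parse_string(s: str, g: Grammar) -> ParseTree:
    """Convenience composition ``parse(tokenize(s, g), g)``."""
    return parse(tokenize(s, g), g)


def leftmost_derivation(t: ParseTree) -> list[int]:
    return t.leftmost_derivation()


def rule_usage_counts(t: ParseTree) -> dict[int, int]:
    return t.rule_usage_counts()
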