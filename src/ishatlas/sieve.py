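"""Boolean sieve: filter genes by tissue-level expression predicates.

A sieve query is a Boolean (AND/OR) combination of per-tissue predicates,
each predicate naming a tissue and the set of expression states it accepts.
Queries are written in a small infix text form::

    T9 is expressed AND T14 is expressed
    T22 in {medium,strong} OR (T23 is strong AND T25 is strong)

``expressed`` is sugar for ``{weak,medium,strong}``.  ``na`` (not analyzed)
satisfies a predicate only when listed explicitly — an unreadable signal is
never silently treated as any expression level.  There is no NOT operator;
complements are taken at the gene-list level against an explicit universe.

Gene lists returned by sieving support union / intersection / complement
algebra, one-id-per-line file I/O and a JSON saved-query store.
"""
from __future__ import annotations

import dataclasses
import json
import re
from collections.abc import Iterable, Sequence
from pathlib import Path

from .annotation import AnnotationMatrix, canonical_gene
from .levels import EXPRESSED_STATES, ExpressionLevel, parse_level


class QuerySyntaxError(ValueError):
    """Sieve query text that does not conform to the grammar."""

    def __init__(self, message: str, pos: int) -> None:
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


@dataclasses.dataclass(frozen=True)
class Predicate:
    """Leaf predicate: the gene's state in `tissue` is one of `states`."""

    tissue: str
    states: frozenset

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("predicate must accept at least one state")
        if not all(isinstance(s, ExpressionLevel) for s in self.states):
            raise TypeError("states must be ExpressionLevel members")


@dataclasses.dataclass(frozen=True)
class And:
    children: tuple

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("AND requires >=2 children")


@dataclasses.dataclass(frozen=True)
class Or:
    children: tuple

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("OR requires >=2 children")


SieveQuery = Predicate | And | Or


# -- parsing ---------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lbrace>\{)|(?P<rbrace>\})|(?P<lparen>\()|(?P<rparen>\))"
    r"|(?P<comma>,)|(?P<word>[^\s(){},]+))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            raise QuerySyntaxError("unexpected character", pos)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str, tissues: Iterable[str] | None) -> None:
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0
        self.tissues = set(tissues) if tissues is not None else None

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of query", len(self.text))
        self.i += 1
        return tok

    def expect(self, kind: str) -> tuple[str, str, int]:
        tok = self.next()
        if tok[0] != kind:
            raise QuerySyntaxError(f"expected {kind}, got {tok[1]!r}", tok[2])
        return tok

    # expr := term (OR term)* ; term := factor (AND factor)*
    def parse(self) -> SieveQuery:
        q = self.expr()
        tok = self.peek()
        if tok is not None:
            raise QuerySyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return q

    def expr(self) -> SieveQuery:
        children = [self.term()]
        while self._keyword("or"):
            children.append(self.term())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def term(self) -> SieveQuery:
        children = [self.factor()]
        while self._keyword("and"):
            children.append(self.factor())
        return children[0] if len(children) == 1 else And(tuple(children))

    def _keyword(self, word: str) -> bool:
        tok = self.peek()
        if tok is not None and tok[0] == "word" and tok[1].lower() == word:
            self.i += 1
            return True
        return False

    def factor(self) -> SieveQuery:
        tok = self.peek()
        if tok is not None and tok[0] == "lparen":
            self.next()
            q = self.expr()
            self.expect("rparen")
            return q
        return self.predicate()

    def predicate(self) -> Predicate:
        kind, tissue, pos = self.next()
        if kind != "word":
            raise QuerySyntaxError(f"expected tissue id, got {tissue!r}", pos)
        if self.tissues is not None and tissue not in self.tissues:
            raise QuerySyntaxError(f"unknown tissue id {tissue!r}", pos)
        kind, op, pos = self.next()
        if kind != "word" or op.lower() not in {"is", "in"}:
            raise QuerySyntaxError(f"expected 'is' or 'in', got {op!r}", pos)
        states = self.states()
        return Predicate(tissue=tissue, states=frozenset(states))

    def states(self) -> set[ExpressionLevel]:
        tok = self.peek()
        if tok is not None and tok[0] == "lbrace":
            self.next()
            out: set[ExpressionLevel] = set()
            while True:
                kind, word, pos = self.next()
                if kind != "word":
                    raise QuerySyntaxError(f"expected state, got {word!r}", pos)
                out |= self._state(word, pos)
                kind, word, pos = self.next()
                if kind == "rbrace":
                    return out
                if kind != "comma":
                    raise QuerySyntaxError(f"expected ',' or '}}', got {word!r}", pos)
        kind, word, pos = self.next()
        if kind != "word":
            raise QuerySyntaxError(f"expected state, got {word!r}", pos)
        return self._state(word, pos)

    @staticmethod
    def _state(word: str, pos: int) -> set[ExpressionLevel]:
        if word.lower() == "expressed":
            return set(EXPRESSED_STATES)
        try:
            return {parse_level(word)}
        except ValueError:
            raise QuerySyntaxError(f"unknown state token {word!r}", pos) from None


def parse_query(expr: str, tissues: Iterable[str] | None = None) -> SieveQuery:
    """Parse sieve query text into a query tree.

    When `tissues` is given, leaf tissue ids are validated against it at
    parse time; otherwise they are checked when the query is applied.
    """
    return _Parser(expr, tissues).parse()


def query_to_text(query: SieveQuery) -> str:
    """Canonical text form of a query tree (re-parseable)."""
    if isinstance(query, Predicate):
        states = query.states
        if states == EXPRESSED_STATES:
            return f"{query.tissue} is expressed"
        if len(states) == 1:
            return f"{query.tissue} is {next(iter(states)).value}"
        ordered = sorted(states, key=lambda s: s.value)
        return f"{query.tissue} in {{{','.join(s.value for s in ordered)}}}"
    sep = " AND " if isinstance(query, And) else " OR "
    parts = []
    for child in query.children:
        text = query_to_text(child)
        if not isinstance(child, Predicate):
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)


# -- JSON serialization and the saved-query store --------------------------

def query_to_dict(query: SieveQuery) -> dict:
    if isinstance(query, Predicate):
        return {
            "tissue": query.tissue,
            "states": sorted(s.value for s in query.states),
        }
    op = "and" if isinstance(query, And) else "or"
    return {"op": op, "children": [query_to_dict(c) for c in query.children]}


def query_from_dict(doc: dict) -> SieveQuery:
    if "tissue" in doc:
        return Predicate(
            tissue=doc["tissue"],
            states=frozenset(parse_level(s) for s in doc["states"]),
        )
    children = tuple(query_from_dict(c) for c in doc["children"])
    return And(children) if doc["op"] == "and" else Or(children)


class QueryStore:
    """Named saved queries persisted as a JSON document on disk."""

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)

    def _load(self) -> dict:
        if not self.path.exists():
            return {}
        return json.loads(self.path.read_text(encoding="utf-8"))

    def save(self, name: str, query: SieveQuery) -> None:
        doc = self._load()
        doc[name] = query_to_dict(query)
        self.path.write_text(json.dumps(doc, indent=2), encoding="utf-8")

    def load(self, name: str) -> SieveQuery:
        doc = self._load()
        if name not in doc:
            raise KeyError(f"no saved query named {name!r}")
        return query_from_dict(doc[name])

    def names(self) -> list[str]:
        return sorted(self._load())


# -- gene lists ------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GeneList:
    """A named set of canonical gene ids with a provenance note."""

    name: str
    members: frozenset
    provenance: str = ""

    @classmethod
    def from_ids(
        cls, ids: Iterable[str], name: str = "", provenance: str = ""
    ) -> "GeneList":
        return cls(
            name=name,
            members=frozenset(canonical_gene(g) for g in ids),
            provenance=provenance,
        )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members))

    def __contains__(self, gene: str) -> bool:
        return canonical_gene(gene) in self.members


def apply_sieve(
    matrix: AnnotationMatrix, query: SieveQuery, name: str = ""
) -> GeneList:
    """Genes of `matrix` whose per-tissue states satisfy the Boolean tree.

    NOT_ANALYZED satisfies a predicate only if explicitly listed in its
    accepted state set.
    """
    frame = matrix.to_frame()

    def evaluate(q: SieveQuery):
        if isinstance(q, Predicate):
            if q.tissue not in frame.columns:
                raise KeyError(f"query references unknown tissue {q.tissue!r}")
            tokens = {s.value for s in q.states}
            return frame[q.tissue].isin(tokens)
        masks = [evaluate(c) for c in q.children]
        out = masks[0]
        for m in masks[1:]:
            out = (out & m) if isinstance(q, And) else (out | m)
        return out

    mask = evaluate(query)
    selected = [g for g, keep in zip(frame.index, mask) if keep]
    return GeneList.from_ids(
        selected, name=name, provenance=f"sieve: {query_to_text(query)}"
    )


class SetOp:
    UNION = "union"
    INTERSECTION = "intersection"
    COMPLEMENT = "complement"


def combine_lists(
    lists: Sequence[GeneList],
    op: str,
    universe: GeneList | None = None,
    name: str = "",
) -> GeneList:
    """Combine gene lists with union / intersection / complement semantics.

    COMPLEMENT removes the union of `lists` from the required `universe`.
    """
    if not lists:
        raise ValueError("need at least one gene list")
    op = op.lower()
    members: frozenset
    if op == SetOp.UNION:
        members = frozenset().union(*(gl.members for gl in lists))
    elif op == SetOp.INTERSECTION:
        members = lists[0].members
        for gl in lists[1:]:
            members = members & gl.members
    elif op == SetOp.COMPLEMENT:
        if universe is None:
            raise ValueError("COMPLEMENT requires a universe gene list")
        removed = frozenset().union(*(gl.members for gl in lists))
        members = universe.members - removed
    else:
        raise ValueError(f"unknown set operation {op!r}")
    operands = ", ".join(gl.name or f"<{len(gl)} genes>" for gl in lists)
    return GeneList(name=name, members=members, provenance=f"{op}({operands})")


# -- file I/O --------------------------------------------------------------

def read_gene_list(path: str | Path, name: str = "") -> GeneList:
    """Read a gene list file: one id per line, ``#`` comments allowed."""
    ids = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return GeneList.from_ids(ids, name=name or Path(path).stem, provenance=str(path))


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        if genes.provenance:
            fh.write(f"# {genes.provenance}\n")
        for g in genes:
            fh.write(g + "\n")
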