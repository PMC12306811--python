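"""Boolean search queries: AND/OR term trees, a PubMed-dialect string form,
and an in-memory retrieval engine over a :class:`LinkedCorpus`.

The engine is a deterministic offline stand-in for a bibliographic search
service.  A study matches a term iff the term's tokens occur as a contiguous,
case-insensitive token subsequence of its title+abstract (phrase matching,
so ``art`` never matches ``heart``); AND intersects and OR unions child
match sets.  Retrieval order is publication date descending with ties broken
by ascending study id, replacing the undocumented relevance order of a live
search engine with something reproducible.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass
from typing import Iterable, Union

from .corpus_model import LinkedCorpus, tokenize
from .errors import LitmineError


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """A search term over the title/abstract field (``tiab``) or all fields."""

    text: str
    field: str = "title_abstract"

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValueError("Term text must be non-empty")
        if self.field not in ("title_abstract", "all"):
            raise ValueError(f"unknown term field: {self.field}")


@dataclass(frozen=True)
class And:
    children: tuple["BooleanQuery", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 1:
            raise ValueError("And requires at least one child")


@dataclass(frozen=True)
class Or:
    children: tuple["BooleanQuery", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 1:
            raise ValueError("Or requires at least one child")


BooleanQuery = Union[Term, And, Or]


def and_(children: Iterable[BooleanQuery]) -> BooleanQuery:
    """AND combinator; a single child collapses to itself."""
    kids = tuple(children)
    return kids[0] if len(kids) == 1 else And(kids)


def or_(children: Iterable[BooleanQuery]) -> BooleanQuery:
    """OR combinator; a single child collapses to itself."""
    kids = tuple(children)
    return kids[0] if len(kids) == 1 else Or(kids)


# ---------------------------------------------------------------------------
# PubMed-dialect serialization
# ---------------------------------------------------------------------------

def serialize_pubmed(query: BooleanQuery) -> str:
    """Render a query in PubMed syntax: quoted terms tagged ``[tiab]``
    (untagged in all-fields mode), upper-case AND/OR, full parentheses."""
    if isinstance(query, Term):
        tag = "[tiab]" if query.field == "title_abstract" else ""
        return f'"{query.text}"{tag}'
    op = " AND " if isinstance(query, And) else " OR "
    if len(query.children) == 1:
        return serialize_pubmed(query.children[0])
    return "(" + op.join(serialize_pubmed(c) for c in query.children) + ")"


class QueryParseError(LitmineError):
    """The PubMed-dialect string could not be parsed."""


_TOKEN_PATTERN = re.compile(
    r'\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<quoted>"[^"]*")'
    r'|(?P<word>[^\s()\[\]"]+))(?P<tag>\[[a-zA-Z ]+\])?'
)


def _lex(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_PATTERN.match(text, pos)
        if not m:
            raise QueryParseError(f"cannot lex query at position {pos}: {text[pos:]!r}")
        if m.group("lparen"):
            tokens.append(("(", "("))
        elif m.group("rparen"):
            tokens.append((")", ")"))
        elif m.group("quoted") is not None:
            term = m.group("quoted")[1:-1]
            field = "title_abstract" if m.group("tag") else "all"
            tokens.append(("term", term) if field == "all" else ("term_tiab", term))
        else:
            word = m.group("word")
            if word.upper() in ("AND", "OR"):
                tokens.append((word.upper(), word.upper()))
            else:
                field_tagged = bool(m.group("tag"))
                tokens.append(("term_tiab" if field_tagged else "term", word))
        pos = m.end()
    return tokens


def parse_pubmed(text: str) -> BooleanQuery:
    """Parse the PubMed dialect produced by :func:`serialize_pubmed`.

    Operators at one nesting level fold left, so mixed AND/OR sequences parse
    without precedence surprises; fully parenthesized input (as produced by
    the serializer) round-trips to an equivalent tree.
    """
    tokens = _lex(text)
    pos = 0

    def parse_atom() -> BooleanQuery:
        nonlocal pos
        if pos >= len(tokens):
            raise QueryParseError("unexpected end of query")
        kind, value = tokens[pos]
        if kind == "(":
            pos += 1
            node = parse_expr()
            if pos >= len(tokens) or tokens[pos][0] != ")":
                raise QueryParseError("missing closing parenthesis")
            pos += 1
            return node
        if kind in ("term", "term_tiab"):
            pos += 1
            field = "title_abstract" if kind == "term_tiab" else "all"
            return Term(value, field=field)
        raise QueryParseError(f"unexpected token {value!r}")

    def parse_expr() -> BooleanQuery:
        nonlocal pos
        node = parse_atom()
        while pos < len(tokens) and tokens[pos][0] in ("AND", "OR"):
            op = tokens[pos][0]
            pos += 1
            rhs = parse_atom()
            if op == "AND":
                if isinstance(node, And):
                    node = And(node.children + (rhs,))
                else:
                    node = And((node, rhs))
            else:
                if isinstance(node, Or):
                    node = Or(node.children + (rhs,))
                else:
                    node = Or((node, rhs))
        return node

    node = parse_expr()
    if pos != len(tokens):
        raise QueryParseError(f"trailing tokens after position {pos}")
    return node


# ---------------------------------------------------------------------------
# Evaluation and retrieval
# ---------------------------------------------------------------------------

_STEM_SUFFIXES = ("ies", "es", "s")


def _stem(token: str) -> str:
    for suf in _STEM_SUFFIXES:
        if token.endswith(suf) and len(token) > len(suf) + 2:
            return token[: -len(suf)] if suf != "ies" else token[:-3] + "y"
    return token


def _phrase_in(needle: tuple[str, ...], haystack: tuple[str, ...]) -> bool:
    n = len(needle)
    if n == 0:
        return False
    if n == 1:
        return needle[0] in haystack
    limit = len(haystack) - n + 1
    first = needle[0]
    for i in range(limit):
        if haystack[i] == first and haystack[i : i + n] == needle:
            return True
    return False


def evaluate(query: BooleanQuery, corpus: LinkedCorpus,
             stem: bool = False) -> set[str]:
    """Ids of corpus studies matching the query.

    With ``stem=True`` a light plural-folding stemmer is applied to both
    query and document tokens; the default is exact token matching.
    """
    index = corpus.token_index()
    if stem:
        index = {sid: tuple(_stem(t) for t in toks) for sid, toks in index.items()}

    def match_ids(node: BooleanQuery) -> set[str]:
        if isinstance(node, Term):
            toks = tokenize(node.text)
            if stem:
                toks = tuple(_stem(t) for t in toks)
            return {sid for sid, doc in index.items() if _phrase_in(toks, doc)}
        child_sets = [match_ids(c) for c in node.children]
        if isinstance(node, And):
            out = child_sets[0]
            for s in child_sets[1:]:
                out = out & s
            return out
        return set().union(*child_sets)

    return match_ids(query)


_OLDEST = datetime.date.min


def retrieve(query: BooleanQuery, corpus: LinkedCorpus, limit: int,
             stem: bool = False) -> list[str]:
    """Matching study ids ordered by publication date descending, ties by
    ascending study id, truncated to ``limit``."""
    if limit < 1:
        raise ValueError("limit must be >= 1")
    matches = evaluate(query, corpus, stem=stem)

    def sort_key(sid: str):
        d = corpus.study(sid).pub_date or _OLDEST
        return (-d.toordinal(), sid)

    return sorted(matches, key=sort_key)[:limit]
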