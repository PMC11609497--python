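"""Selection-expression language: a small VMD-like grammar.

EBNF (also in docs/selection-grammar.md)::

    expr     = or_expr ;
    or_expr  = and_expr , { "or" , and_expr } ;
    and_expr = unary , { "and" , unary } ;
    unary    = "not" , unary | primary ;
    primary  = "(" , expr , ")"
             | "all"
             | "name"    , word , { word }
             | "resname" , word , { word }
             | "chain"   , word , { word }
             | "resid"   , range , { range }
             | "index"   , range , { range }
             | "within"  , number , "of" , "(" , expr , ")" ;
    range    = integer , [ ( "-" | "to" ) , integer ] ;

`index` ranges are 0-based inclusive; `resid` uses the file's residue ids
verbatim.  `within r of (E)` selects every atom of the whole system whose
minimum-image distance to any atom matched by E is <= r (in nm); whether the
atoms of E themselves are included is controlled by the evaluation flag
``include_self`` (default True).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParseError

__all__ = ["parse", "EvalContext"]

_KEYWORDS = {"all", "name", "resname", "resid", "chain", "index",
             "within", "of", "and", "or", "not", "to"}

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lparen>\()|(?P<rparen>\))"
    r"|(?P<num>\d+\.\d*|\.\d+|\d+)"
    r"|(?P<dash>-)"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_'*+]*))"
)


@dataclass
class _Token:
    kind: str   # lparen | rparen | num | dash | word | end
    text: str
    pos: int


def _tokenize(expr: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {expr[pos:].lstrip()[0]!r}",
                             pos=len(expr) - len(expr[pos:].lstrip()))
        kind = m.lastgroup
        tokens.append(_Token(kind, m.group(kind), m.start(kind)))
        pos = m.end()
    tokens.append(_Token("end", "", len(expr)))
    return tokens


class EvalContext:
    """Everything a node needs to evaluate against one system frame."""

    def __init__(self, topology, state, include_self: bool = True):
        cols = topology._columns()
        self.names = cols["name"]
        self.resnames = cols["resname"]
        self.resids = cols["resid"]
        self.chains = cols["chain"]
        self.coords = state.coords
        self.box = state.box
        self.n_atoms = topology.n_atoms
        self.include_self = include_self


class Node:
    def evaluate(self, ctx: EvalContext, cand: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _All(Node):
    def evaluate(self, ctx, cand):
        return np.ones(len(cand), dtype=bool)


class _FieldIn(Node):
    """name/resname/chain membership test."""

    def __init__(self, field: str, values: list[str]):
        self.field = field
        self.values = set(values)

    def evaluate(self, ctx, cand):
        col = {"name": ctx.names, "resname": ctx.resnames, "chain": ctx.chains}[self.field]
        vals = self.values
        return np.fromiter((v in vals for v in col[cand]), dtype=bool, count=len(cand))


class _RangeIn(Node):
    """resid/index range test; ranges are inclusive."""

    def __init__(self, field: str, ranges: list[tuple[int, int]]):
        self.field = field
        self.ranges = ranges

    def evaluate(self, ctx, cand):
        vals = cand if self.field == "index" else ctx.resids[cand]
        mask = np.zeros(len(cand), dtype=bool)
        for lo, hi in self.ranges:
            mask |= (vals >= lo) & (vals <= hi)
        return mask


class _Within(Node):
    def __init__(self, radius: float, inner: Node):
        self.radius = radius
        self.inner = inner

    def evaluate(self, ctx, cand):
        from .neighbor import search_within  # local: avoid import cycle
        everything = np.arange(ctx.n_atoms)
        inner_mask = self.inner.evaluate(ctx, everything)
        query = everything[inner_mask]
        if query.size == 0:
            return np.zeros(len(cand), dtype=bool)
        hits = search_within(ctx.coords, query, self.radius, box=ctx.box,
                             include_query=ctx.include_self)
        return np.isin(cand, hits)


class _Not(Node):
    def __init__(self, inner: Node):
        self.inner = inner

    def evaluate(self, ctx, cand):
        return ~self.inner.evaluate(ctx, cand)


class _Bool(Node):
    def __init__(self, op: str, parts: list[Node]):
        self.op = op
        self.parts = parts

    def evaluate(self, ctx, cand):
        mask = self.parts[0].evaluate(ctx, cand)
        for p in self.parts[1:]:
            if self.op == "and":
                mask = mask & p.evaluate(ctx, cand)
            else:
                mask = mask | p.evaluate(ctx, cand)
        return mask


class _Parser:
    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def next(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str, text: Optional[str] = None) -> _Token:
        tok = self.next()
        if tok.kind != kind or (text is not None and tok.text != text):
            want = text or kind
            raise ParseError(f"expected {want!r}, found {tok.text or 'end of input'!r}",
                             pos=tok.pos)
        return tok

    def parse(self) -> Node:
        node = self.or_expr()
        tok = self.peek()
        if tok.kind != "end":
            raise ParseError(f"unexpected trailing input {tok.text!r}", pos=tok.pos)
        return node

    def or_expr(self) -> Node:
        parts = [self.and_expr()]
        while self.peek().kind == "word" and self.peek().text == "or":
            self.next()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else _Bool("or", parts)

    def and_expr(self) -> Node:
        parts = [self.unary()]
        while self.peek().kind == "word" and self.peek().text == "and":
            self.next()
            parts.append(self.unary())
        return parts[0] if len(parts) == 1 else _Bool("and", parts)

    def unary(self) -> Node:
        tok = self.peek()
        if tok.kind == "word" and tok.text == "not":
            self.next()
            return _Not(self.unary())
        return self.primary()

    def primary(self) -> Node:
        tok = self.next()
        if tok.kind == "lparen":
            node = self.or_expr()
            self.expect("rparen")
            return node
        if tok.kind != "word":
            raise ParseError(f"expected a keyword, found {tok.text or 'end of input'!r}",
                             pos=tok.pos)
        kw = tok.text
        if kw == "all":
            return _All()
        if kw in ("name", "resname", "chain"):
            return _FieldIn(kw, self.word_list(kw))
        if kw in ("resid", "index"):
            return _RangeIn(kw, self.range_list(kw))
        if kw == "within":
            num = self.expect("num")
            self.expect("word", "of")
            self.expect("lparen")
            inner = self.or_expr()
            self.expect("rparen")
            return _Within(float(num.text), inner)
        raise ParseError(f"unknown keyword {kw!r}", pos=tok.pos)

    def word_list(self, kw: str) -> list[str]:
        values: list[str] = []
        while True:
            tok = self.peek()
            if tok.kind in ("word", "num") and tok.text not in _KEYWORDS:
                values.append(self.next().text)
            else:
                break
        if not values:
            raise ParseError(f"{kw!r} needs at least one value", pos=self.peek().pos)
        return values

    def range_list(self, kw: str) -> list[tuple[int, int]]:
        ranges: list[tuple[int, int]] = []
        while self.peek().kind == "num":
            lo = int(self.next().text)
            hi = lo
            tok = self.peek()
            if tok.kind == "dash" or (tok.kind == "word" and tok.text == "to"):
                self.next()
                hi = int(self.expect("num").text)
            if hi < lo:
                raise ParseError(f"descending range {lo}-{hi}", pos=tok.pos)
            ranges.append((lo, hi))
        if not ranges:
            raise ParseError(f"{kw!r} needs at least one number or range",
                             pos=self.peek().pos)
        return ranges


def parse(expr: str) -> Node:
    """Parse a selection expression into an evaluatable AST."""
    if not expr or not expr.strip():
        raise ParseError("empty selection expression", pos=0)
    return _Parser(expr).parse()
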