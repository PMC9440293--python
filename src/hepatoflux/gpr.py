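"""Gene-protein-reaction (GPR) rules: parsing and numeric evaluation.

A GPR rule is a boolean expression over gene identifiers, e.g.
``"(g1 and g2) or g3"``.  Isoenzymes (OR) add their capacities, enzyme
complexes (AND) are limited by their scarcest subunit, so the numeric
evaluation convention used for expression integration is AND = min,
OR = sum (with OR = max available as an alternative).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = ["GeneRule", "parse_gpr", "eval_gpr"]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class GeneRule:
    """Boolean expression tree over gene ids.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``; leaves carry the gene
    id in ``gene``; internal nodes carry ``children``.  The empty rule is
    represented by ``GeneRule.EMPTY`` (op ``"empty"``).
    """

    op: str
    gene: str | None = None
    children: tuple["GeneRule", ...] = ()

    EMPTY: "GeneRule" = None  # type: ignore[assignment]

    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> frozenset[str]:
        """All gene ids appearing as leaves."""
        if self.op == "gene":
            return frozenset((self.gene,))
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def to_string(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op in ("and", "or") and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


GeneRule.EMPTY = GeneRule(op="empty")


def _tokens(rule: str) -> Iterator[str]:
    for tok in _TOKEN_RE.findall(rule):
        yield tok


class _Parser:
    """Recursive-descent parser; OR binds looser than AND."""

    def __init__(self, rule: str):
        self.toks = list(_tokens(rule))
        self.pos = 0
        self.src = rule

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def next(self) -> str:
        tok = self.toks[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> GeneRule:
        node = self.parse_or()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens in GPR rule {self.src!r}")
        return node

    def parse_or(self) -> GeneRule:
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.parse_and())
        if len(terms) == 1:
            return terms[0]
        return GeneRule(op="or", children=tuple(terms))

    def parse_and(self) -> GeneRule:
        terms = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            terms.append(self.parse_atom())
        if len(terms) == 1:
            return terms[0]
        return GeneRule(op="and", children=tuple(terms))

    def parse_atom(self) -> GeneRule:
        tok = self.peek()
        if tok is None:
            raise ValueError(f"unexpected end of GPR rule {self.src!r}")
        if tok == "(":
            self.next()
            node = self.parse_or()
            if self.peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR rule {self.src!r}")
            self.next()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"malformed GPR rule {self.src!r}")
        self.next()
        return GeneRule(op="gene", gene=tok)


def parse_gpr(rule: str | None) -> GeneRule:
    """Parse a GPR string into a :class:`GeneRule` tree.

    Blank / ``None`` input yields the empty rule.  ``and``/``or`` are
    case-insensitive; any other token is a gene identifier.
    """
    if rule is None or not rule.strip():
        return GeneRule.EMPTY
    return _Parser(rule).parse()


def eval_gpr(
    rule: GeneRule,
    gene_values: Mapping[str, float],
    or_mode: str = "sum",
) -> float | None:
    """Evaluate a GPR rule numerically against per-gene expression values.

    AND combines by minimum (complex limited by scarcest subunit); OR by sum
    of isoenzyme capacities (``or_mode="max"`` switches to maximum).  Genes
    absent from ``gene_values`` are imputed as the smallest positive value
    present (a conservative floor).  The empty rule evaluates to ``None``
    (no evidence), never 0.
    """
    if rule.is_empty:
        return None
    if or_mode not in ("sum", "max"):
        raise ValueError(f"or_mode must be 'sum' or 'max', got {or_mode!r}")
    floor = None

    def impute() -> float:
        nonlocal floor
        if floor is None:
            positives = [v for v in gene_values.values() if v > 0]
            floor = min(positives) if positives else 0.0
        return floor

    def ev(node: GeneRule) -> float:
        if node.op == "gene":
            v = gene_values.get(node.gene)
            return impute() if v is None else float(v)
        vals = [ev(c) for c in node.children]
        if node.op == "and":
            return min(vals)
        return sum(vals) if or_mode == "sum" else max(vals)

    return ev(rule)
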