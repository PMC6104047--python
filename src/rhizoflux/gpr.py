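"""Gene-protein-reaction (GPR) boolean rules.

Rules are boolean expressions over gene identifiers, e.g.
``g1 and (g2 or g3)``.  For expression-based scoring, OR maps to ``max``
(isozymes: the strongest isozyme carries the reaction) and AND to ``min``
(complex subunits: the weakest subunit limits it).
"""

from __future__ import annotations

import re
from typing import Callable, Mapping

__all__ = ["parse_gpr", "gpr_genes", "evaluate_gpr", "GPRSyntaxError"]


class GPRSyntaxError(ValueError):
    pass


_TOKEN = re.compile(r"\s*(\(|\)|\band\b|\bor\b|&&?|\|\|?|[^\s()&|]+)", re.IGNORECASE)


def _tokenize(rule: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if m is None:
            break
        tok = m.group(1)
        low = tok.lower()
        if low in ("and", "&", "&&"):
            tokens.append("and")
        elif low in ("or", "|", "||"):
            tokens.append("or")
        else:
            tokens.append(tok)
        pos = m.end()
    if rule[pos:].strip():
        raise GPRSyntaxError(f"cannot tokenize GPR {rule!r} at {pos}")
    return tokens


# AST: gene id (str) | ("and", [children]) | ("or", [children])
Node = object


def parse_gpr(rule: str) -> Node:
    """Parse a GPR rule into a small AST.  OR binds looser than AND."""
    tokens = _tokenize(rule)
    if not tokens:
        raise GPRSyntaxError("empty GPR rule")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> Node:
        nonlocal pos
        terms = [parse_and()]
        while peek() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and() -> Node:
        nonlocal pos
        terms = [parse_atom()]
        while peek() == "and":
            pos += 1
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom() -> Node:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR {rule!r}")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in GPR {rule!r}")
            pos += 1
            return node
        if tok in (")", "and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in GPR {rule!r}")
        pos += 1
        return tok

    node = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in GPR {rule!r}")
    return node


def gpr_genes(rule: str) -> set[str]:
    out: set[str] = set()

    def walk(node: Node) -> None:
        if isinstance(node, str):
            out.add(node)
        else:
            for child in node[1]:
                walk(child)

    walk(parse_gpr(rule))
    return out


def evaluate_gpr(
    rule: str,
    gene_values: Mapping[str, float],
    missing: Callable[[str], float] | float = 0.0,
) -> float:
    """Score a rule against gene expression values (OR→max, AND→min).

    Genes absent from the table score ``missing`` (default 0, i.e. not
    expressed).
    """

    def value(gene: str) -> float:
        if gene in gene_values:
            return float(gene_values[gene])
        if callable(missing):
            return missing(gene)
        return float(missing)

    def walk(node: Node) -> float:
        if isinstance(node, str):
            return value(node)
        op, children = node
        vals = [walk(c) for c in children]
        return max(vals) if op == "or" else min(vals)

    return walk(parse_gpr(rule))
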