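"""A small atom-selection grammar.

Supported primaries::

    resid 63            resid 60:70          resid 63 65 68
    resname DHA POPC    name CA CB           chain A
    protein             lipid                other
    sidechain           all

combined with ``and``, ``or``, ``not`` and parentheses.  ``sidechain``
selects heavy atoms excluding the backbone N, CA, C, O (and terminal
oxygens); a glycine therefore contributes nothing and a selection that
matches no atom returns an empty group with a warning rather than an
error.
"""

from __future__ import annotations

import re
import warnings

import numpy as np

from .core import AtomGroup, BACKBONE_NAMES, Topology

__all__ = ["select", "SelectionError"]


class SelectionError(ValueError):
    """Raised for a syntactically invalid selection expression."""


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORDS = {
    "and", "or", "not", "resid", "resname", "name", "chain",
    "protein", "lipid", "other", "sidechain", "all",
}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens = []
    for m in _TOKEN_RE.finditer(expression):
        tokens.append((m.group(0), m.start()))
    return tokens


class _Parser:
    """Recursive-descent parser producing a boolean mask over atoms.

    Precedence (loosest to tightest): or, and, not, primary.
    """

    def __init__(self, topology: Topology, tokens: list[tuple[str, int]], text: str):
        self.top = topology
        self.tokens = tokens
        self.pos = 0
        self.text = text

    def _peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        if self.pos >= len(self.tokens):
            raise SelectionError(
                f"unexpected end of selection {self.text!r}"
            )
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def _error(self, msg: str, offset: int) -> SelectionError:
        return SelectionError(f"{msg} at position {offset} in {self.text!r}")

    def parse(self) -> np.ndarray:
        mask = self._or_expr()
        if self.pos < len(self.tokens):
            tok, off = self.tokens[self.pos]
            raise self._error(f"unexpected token {tok!r}", off)
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek() == "or":
            self._next()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._not_expr()
        while self._peek() == "and":
            self._next()
            mask = mask & self._not_expr()
        return mask

    def _not_expr(self) -> np.ndarray:
        if self._peek() == "not":
            self._next()
            return ~self._not_expr()
        return self._primary()

    def _values(self) -> list[tuple[str, int]]:
        """Greedily consume value tokens (anything that is not a keyword
        or a parenthesis)."""
        vals = []
        while True:
            tok = self._peek()
            if tok is None or tok in _KEYWORDS or tok in "()":
                break
            vals.append(self._next())
        return vals

    def _primary(self) -> np.ndarray:
        tok, off = self._next()
        top = self.top
        n = top.n_atoms
        if tok == "(":
            mask = self._or_expr()
            closing, coff = self._next()
            if closing != ")":
                raise self._error("expected ')'", coff)
            return mask
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok in ("protein", "lipid", "other"):
            return top.molecule_kinds == tok
        if tok == "sidechain":
            heavy = np.array([e != "H" for e in top.elements])
            backbone = np.array([a in BACKBONE_NAMES for a in top.atom_names])
            return (top.molecule_kinds == "protein") & heavy & ~backbone
        if tok == "resid":
            vals = self._values()
            if not vals:
                raise self._error("resid needs at least one number", off)
            mask = np.zeros(n, dtype=bool)
            for v, voff in vals:
                m = re.fullmatch(r"(-?\d+)(?::(-?\d+))?", v)
                if not m:
                    raise self._error(f"bad residue number {v!r}", voff)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                mask |= (top.residue_numbers >= lo) & (top.residue_numbers <= hi)
            return mask
        if tok in ("resname", "name", "chain"):
            vals = self._values()
            if not vals:
                raise self._error(f"{tok} needs at least one value", off)
            attr = {
                "resname": top.residue_names,
                "name": top.atom_names,
                "chain": top.chain_ids,
            }[tok]
            wanted = {v for v, _ in vals}
            return np.array([a in wanted for a in attr])
        raise self._error(f"unknown token {tok!r}", off)


def select(topology: Topology, expression: str, label: str | None = None) -> AtomGroup:
    """Evaluate a selection expression against a topology.

    Deterministic and order-independent: the result is the sorted set of
    matching atom ids.  An empty result warns and returns an empty group.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(topology, tokens, expression).parse()
    ids = np.flatnonzero(mask)
    if len(ids) == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return AtomGroup(topology, ids, label if label is not None else expression)
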