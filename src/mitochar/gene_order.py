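"""Signed circular gene orders and rearrangement analysis.

A mitochondrial gene order is a circular sequence of signed tokens over the
37-gene vocabulary plus ``CR`` (sign = transcriptional orientation;
duplicated genes carry ``#2``-style occurrence suffixes). Orders compare by
signed circular adjacency: the breakpoint distance counts adjacencies of the
derived order absent from the reference. Event detection searches
exhaustively for the smallest gene set whose removal makes the two orders
identical up to rotation — the implicated (translocated and/or inverted)
genes — and a single tandem-duplication/random-loss (TDRL) event is accepted
as an explanation exactly when the derived tokens, indexed by their
reference positions, decompose into at most two increasing contiguous
blocks (one round of "duplicate the span in tandem, lose one copy of each
gene"; a TDRL never changes orientation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .annotation_io import MitoAnnotation

__all__ = [
    "GeneOrder",
    "RearrangementReport",
    "order_from_annotation",
    "breakpoint_distance",
    "detect_events",
    "apply_events",
    "tdrl_one_step",
    "load_named_orders",
    "linear_map",
]

Token = tuple[str, int]  # (gene token, orientation +1/-1)


@dataclass(frozen=True)
class GeneOrder:
    """A signed circular token sequence."""

    tokens: tuple[Token, ...]
    anchor: str = "cox1"

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("gene order must be nonempty")

    # -- construction ----------------------------------------------------
    @classmethod
    def from_string(cls, text: str, anchor: str = "cox1") -> "GeneOrder":
        """Parse a comma-separated signed token string.

        A leading ``-`` marks the light strand, e.g.
        ``"cox1,cox2,trnL2,-nad1"``. Whitespace and an optional explicit
        ``+`` are tolerated.
        """
        tokens = []
        for item in text.split(","):
            item = item.strip().rstrip(";")
            if not item:
                continue
            sign = 1
            if item[0] in "+-":
                sign = -1 if item[0] == "-" else 1
                item = item[1:].strip()
            tokens.append((item, sign))
        return cls(tuple(tokens), anchor=anchor)

    def to_string(self) -> str:
        return ",".join(("-" if s < 0 else "") + n for n, s in self.tokens)

    # -- basic views -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.tokens)

    def multiplicity(self, base: str) -> int:
        return sum(1 for n, _ in self.tokens if n.partition("#")[0] == base)

    def rotated(self, k: int) -> "GeneOrder":
        k %= len(self.tokens)
        return GeneOrder(self.tokens[k:] + self.tokens[:k], anchor=self.anchor)

    def normalized(self) -> "GeneOrder":
        """Deterministic rotation: anchor gene first (with + orientation
        preferred), falling back to the lexicographically minimal rotation."""
        candidates = [i for i, (n, s) in enumerate(self.tokens)
                      if n == self.anchor]
        if candidates:
            plus = [i for i in candidates if self.tokens[i][1] > 0]
            return self.rotated((plus or candidates)[0])
        best = min(range(len(self.tokens)),
                   key=lambda k: self.rotated(k).tokens)
        return self.rotated(best)

    def restrict(self, names: Iterable[str]) -> "GeneOrder":
        keep = set(names)
        kept = tuple(t for t in self.tokens if t[0] in keep)
        return GeneOrder(kept, anchor=self.anchor)

    def adjacencies(self) -> set[tuple[Token, Token]]:
        """Signed circular adjacency set (empty for a single token)."""
        if len(self.tokens) < 2:
            return set()
        return {(self.tokens[i], self.tokens[(i + 1) % len(self.tokens)])
                for i in range(len(self.tokens))}

    # -- editing (used by the synthetic generator and event round-trips) --
    def remove(self, names: Iterable[str]) -> "GeneOrder":
        drop = set(names)
        return GeneOrder(tuple(t for t in self.tokens if t[0] not in drop),
                         anchor=self.anchor)

    def insert_after(self, name: str, sign: int, after: str) -> "GeneOrder":
        toks = list(self.tokens)
        idx = [i for i, (n, _) in enumerate(toks) if n == after]
        if not idx:
            raise KeyError(after)
        toks.insert(idx[0] + 1, (name, sign))
        return GeneOrder(tuple(toks), anchor=self.anchor)

    def translocate(self, name: str, after: str) -> "GeneOrder":
        sign = dict(self.tokens)[name]
        return self.remove([name]).insert_after(name, sign, after)

    def invert(self, name: str) -> "GeneOrder":
        toks = tuple((n, -s if n == name else s) for n, s in self.tokens)
        return GeneOrder(toks, anchor=self.anchor)

    def duplicate(self, name: str, after: Optional[str] = None) -> "GeneOrder":
        """Insert a second copy (occurrence-suffixed) after ``after``
        (default: in tandem after the original)."""
        sign = dict(self.tokens)[name]
        occ = 2
        while any(n == f"{name}#{occ}" for n, _ in self.tokens):
            occ += 1
        return self.insert_after(f"{name}#{occ}", sign, after or name)


def rotation_equal(a: GeneOrder, b: GeneOrder) -> bool:
    if len(a) != len(b):
        return False
    return any(a.rotated(k).tokens == b.tokens for k in range(len(a)))


def order_from_annotation(ann: MitoAnnotation,
                          anchor: str = "cox1") -> GeneOrder:
    """Gene order of an annotation: features by start position (circular),
    CR included as a positional token, orientation from strand."""
    feats = sorted(ann.features, key=lambda f: (f.start, f.end))
    return GeneOrder(tuple((f.name, f.strand) for f in feats), anchor=anchor)


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------

def _shared(derived: GeneOrder, reference: GeneOrder
            ) -> tuple[GeneOrder, GeneOrder, set[str]]:
    shared = set(derived.names) & set(reference.names)
    skipped = (set(derived.names) | set(reference.names)) - shared
    if not shared:
        raise ValueError("no shared tokens between the two orders")
    return derived.restrict(shared), reference.restrict(shared), skipped


def breakpoint_distance(derived: GeneOrder, reference: GeneOrder) -> int:
    """Signed circular adjacencies of ``derived`` absent from ``reference``.

    Tokens present on only one side are skipped. Zero iff the orders are
    identical up to rotation; invariant under rotation of either order.
    """
    d, r, _ = _shared(derived, reference)
    return len(d.adjacencies() - r.adjacencies())


@dataclass(frozen=True)
class RearrangementReport:
    breakpoints: int
    translocated: tuple[str, ...]          # minimal implicated gene set
    inverted: tuple[str, ...]              # orientation changes (CR excluded)
    duplicated: tuple[str, ...]            # extra copies in the derived order
    tdrl_one_step: bool
    tdrl_reason: str = ""
    complex: bool = False                  # no solution within max_moved
    # (gene, sign in derived, predecessor in derived) for each moved gene,
    # enough to replay the translocations onto the reference
    placements: tuple[tuple[str, int, str], ...] = ()


def detect_events(derived: GeneOrder, reference: GeneOrder,
                  max_moved: int = 3) -> RearrangementReport:
    """Minimal rearrangement events separating two gene orders.

    Exhaustive search over gene subsets of size <= ``max_moved`` whose
    removal makes the orders rotation-equal (ignoring orientation for the
    removed genes). Ties between equally small subsets are broken in favor
    of fewer protein-coding/rRNA genes (tRNA translocations being the
    common mitochondrial mechanism), then lexicographically.
    """
    d_all, r_all, _ = _shared(derived, reference)
    duplicated = tuple(sorted(
        {n.partition("#")[0] for n in derived.names
         if derived.multiplicity(n.partition("#")[0])
         > reference.multiplicity(n.partition("#")[0])}))
    # orientation comparison for tokens appearing once in each order
    inverted = []
    d_signs = dict(d_all.tokens)
    r_signs = dict(r_all.tokens)
    for name in set(d_signs) & set(r_signs):
        if name == "CR" or d_all.multiplicity(name.partition("#")[0]) > 1:
            continue
        if d_signs[name] != r_signs[name]:
            inverted.append(name)
    inverted = tuple(sorted(inverted))

    breakpoints = len(d_all.adjacencies() - r_all.adjacencies())
    translocated: Optional[tuple[str, ...]] = None
    from .annotation_io import infer_ftype

    def cost(subset: tuple[str, ...]) -> tuple:
        heavy = sum(1 for g in subset
                    if infer_ftype(g) in ("PCG", "rRNA"))
        return (heavy, subset)

    names = sorted(set(d_all.names))
    for k in range(0, max_moved + 1):
        hits = []
        for subset in itertools.combinations(names, k):
            d_cut = d_all.remove(subset)
            r_cut = r_all.remove(subset)
            if len(d_cut) == 0:
                if len(r_cut) == 0:
                    hits.append(subset)
                continue
            # orientation of non-removed genes must match exactly
            if rotation_equal(d_cut, r_cut):
                hits.append(subset)
        if hits:
            translocated = min(hits, key=cost)
            break

    if translocated is None:
        tdrl, reason = tdrl_one_step(d_all.normalized(), r_all.normalized())
        return RearrangementReport(breakpoints, (), inverted, duplicated,
                                   tdrl, reason, complex=True)

    placements = []
    moved = set(translocated)
    d_tokens = d_all.normalized().tokens
    for i, (name, sign) in enumerate(d_tokens):
        if name in moved:
            j = (i - 1) % len(d_tokens)
            while d_tokens[j][0] in moved:
                j = (j - 1) % len(d_tokens)
            placements.append((name, sign, d_tokens[j][0]))
    tdrl, reason = tdrl_one_step(d_all.normalized(), r_all.normalized())
    return RearrangementReport(breakpoints, translocated, inverted,
                               duplicated, tdrl, reason,
                               placements=tuple(placements))


def apply_events(reference: GeneOrder,
                 report: RearrangementReport) -> GeneOrder:
    """Replay the reported translocations onto the reference order."""
    order = reference.remove(report.translocated)
    for name, sign, after in report.placements:
        order = order.insert_after(name, sign, after)
    return order


# ---------------------------------------------------------------------------
# TDRL
# ---------------------------------------------------------------------------

def tdrl_one_step(derived: GeneOrder, reference: GeneOrder,
                  segment: Optional[Iterable[str]] = None
                  ) -> tuple[bool, str]:
    """Can one tandem-duplication/random-loss event explain the derived span?

    The compared span (default: all shared tokens) is read linearly in the
    order given — callers comparing whole circles should normalize both
    orders to a common anchor first. After one tandem duplication of the
    span, losing one copy of each gene leaves the genes kept from the first
    copy (in reference order) followed by those kept from the second copy
    (also in reference order). Mapping the derived tokens to their reference
    indices, a single TDRL is therefore possible iff the index sequence
    splits into at most two increasing contiguous blocks — equivalently it
    has at most one descent. TDRL never inverts, so any orientation mismatch
    in the span is an immediate negative.
    """
    d, r, _ = _shared(derived, reference)
    if segment is not None:
        seg = set(segment)
        d, r = d.restrict(seg), r.restrict(seg)
        if not len(d) or set(d.names) != set(r.names):
            raise ValueError("segment tokens must be present in both orders")
    if set(d.names) != set(r.names) or len(d) != len(r):
        raise ValueError("TDRL test requires identical token sets")
    d_signs, r_signs = dict(d.tokens), dict(r.tokens)
    if any(d_signs[n] != r_signs[n] for n in d_signs):
        return False, "TDRL cannot invert"
    index_in_ref = {name: i for i, (name, _) in enumerate(r.tokens)}
    seq = [index_in_ref[name] for name, _ in d.tokens]
    descents = sum(1 for i in range(len(seq) - 1) if seq[i] > seq[i + 1])
    if descents <= 1:
        return True, ""
    return False, "derived span needs more than two reference-ordered blocks"


# ---------------------------------------------------------------------------
# Named references and text maps
# ---------------------------------------------------------------------------

def load_named_orders() -> dict[str, GeneOrder]:
    """Built-in named gene orders (ancestral patterns and published
    rearrangements), from the bundled reference file."""
    from .annotation_io import _DATA_DIR

    orders: dict[str, GeneOrder] = {}
    for line in (_DATA_DIR / "gene_orders.tsv").read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("Name\t"):
            continue
        name, text = line.split("\t", 1)
        orders[name.strip()] = GeneOrder.from_string(text)
    return orders


def linear_map(order: GeneOrder, width: int = 100) -> str:
    """Plain-text linear gene-arrangement map (normalized rotation).

    Light-strand genes are bracketed, mirroring figure conventions where
    orientation is drawn rather than signed.
    """
    cells = [(name if sign > 0 else f"({name})")
             for name, sign in order.normalized().tokens]
    lines, cur = [], ""
    for cell in cells:
        if cur and len(cur) + len(cell) + 3 > width:
            lines.append(cur + " >")
            cur = ""
        cur = f"{cur} {cell}" if cur else cell
    if cur:
        lines.append(cur)
    return "\n".join(lines)
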