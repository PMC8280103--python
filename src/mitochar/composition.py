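"""Base composition, strand skews, and circular adjacency accounting.

Strand asymmetry follows the standard definitions
``AT-skew = (A - T)/(A + T)`` and ``GC-skew = (G - C)/(G + C)``; both are
scale-invariant, so they accept raw counts or percentages. The whole-genome
row is computed on the heavy strand; single-gene and class rows (PCGs, tRNAs,
rRNAs) are computed on each gene's reading sense, concatenated in annotation
order — the convention that reproduces published composition tables for
mitogenomes with genes on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .annotation_io import (
    AnnotationError,
    GeneFeature,
    MitoAnnotation,
    reverse_complement,
)

__all__ = [
    "CompositionRecord",
    "Adjacency",
    "AdjacencyReport",
    "skew",
    "sequence_composition",
    "region_composition",
    "composition_report",
    "adjacency_report",
    "CLASS_SELECTORS",
]

CLASS_SELECTORS = ("all", "PCGs", "tRNAs", "rRNAs", "CR")


class SkewUndefinedError(ZeroDivisionError):
    """Raised when a skew denominator is zero."""


def skew(x: float, y: float) -> float:
    """(x - y)/(x + y); antisymmetric, zero iff x == y."""
    if x + y == 0:
        raise SkewUndefinedError("skew undefined for x + y = 0")
    return (x - y) / (x + y)


@dataclass(frozen=True)
class CompositionRecord:
    """Counts, percentages and skews for one region row."""

    region_label: str
    size: int                       # counted A+C+G+T bases
    counts: dict                    # A/T/G/C tallies
    n_ambiguous: int = 0            # N bases, excluded from size and skews

    @property
    def pct(self) -> dict:
        return {b: 100.0 * self.counts[b] / self.size for b in "ATGC"}

    @property
    def at_content(self) -> float:
        return 100.0 * (self.counts["A"] + self.counts["T"]) / self.size

    @property
    def at_skew(self) -> float:
        return skew(self.counts["A"], self.counts["T"])

    @property
    def gc_skew(self) -> float:
        return skew(self.counts["G"], self.counts["C"])


def sequence_composition(label: str, seq: str) -> CompositionRecord:
    counts = {b: seq.count(b) for b in "ATGC"}
    size = sum(counts.values())
    if size == 0:
        raise AnnotationError(f"{label}: no unambiguous bases")
    return CompositionRecord(label, size, counts,
                             n_ambiguous=len(seq) - size)


def region_composition(ann: MitoAnnotation,
                       region: str) -> CompositionRecord:
    """Composition record for a gene name or a region class.

    ``region`` is a feature name, or one of ``all`` (whole heavy strand),
    ``PCGs``/``tRNAs``/``rRNAs`` (reading-sense concatenation of member
    genes in annotation order) or ``CR``.
    """
    if ann.sequence is None:
        raise AnnotationError("region_composition requires a sequence")
    if region == "all":
        return sequence_composition("Mitogenome", ann.sequence)
    if region in ("PCGs", "tRNAs", "rRNAs"):
        ftype = {"PCGs": "PCG", "tRNAs": "tRNA", "rRNAs": "rRNA"}[region]
        members = ann.features_of_type(ftype)
        if not members:
            raise AnnotationError(f"no features of class {region}")
        seq = "".join(ann.reading_sense(f) for f in members)
        return sequence_composition(region, seq)
    # single feature (CR included)
    try:
        feat = ann.feature(region)
    except KeyError:
        raise AnnotationError(f"selector {region!r} matches no feature")
    return sequence_composition(feat.name, ann.reading_sense(feat))


def composition_report(ann: MitoAnnotation,
                       regions: Optional[Sequence[str]] = None,
                       ndigits_pct: int = 2,
                       ndigits_skew: int = 3) -> pd.DataFrame:
    """Composition table: whole genome, each PCG, then the class rows.

    Rounding (percent 2 dp, skew 3 dp) happens only here, at serialization.
    """
    if regions is None:
        regions = (["all"]
                   + [f.name for f in ann.features_of_type("PCG")]
                   + ["PCGs", "tRNAs", "rRNAs"]
                   + (["CR"] if any(f.ftype == "CR" for f in ann.features)
                      else []))
    rows = []
    for region in regions:
        rec = region_composition(ann, region)
        rows.append({
            "Region": rec.region_label,
            "Size": rec.size + rec.n_ambiguous,
            "A": round(rec.pct["A"], ndigits_pct),
            "T": round(rec.pct["T"], ndigits_pct),
            "G": round(rec.pct["G"], ndigits_pct),
            "C": round(rec.pct["C"], ndigits_pct),
            "AT": round(rec.at_content, ndigits_pct),
            "AT_skew": round(rec.at_skew, ndigits_skew),
            "GC_skew": round(rec.gc_skew, ndigits_skew),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Circular adjacency accounting (spacers / overlaps)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Adjacency:
    upstream: str
    downstream: str
    gap_bp: int  # > 0 spacer, < 0 overlap of |gap_bp| bp, 0 abutting


@dataclass(frozen=True)
class AdjacencyReport:
    pairs: tuple[Adjacency, ...]

    @property
    def n_spacers(self) -> int:
        return sum(1 for p in self.pairs if p.gap_bp > 0)

    @property
    def n_overlaps(self) -> int:
        return sum(1 for p in self.pairs if p.gap_bp < 0)

    @property
    def largest_spacer(self) -> Optional[Adjacency]:
        spacers = [p for p in self.pairs if p.gap_bp > 0]
        return max(spacers, key=lambda p: p.gap_bp) if spacers else None

    @property
    def largest_overlap(self) -> Optional[Adjacency]:
        overlaps = [p for p in self.pairs if p.gap_bp < 0]
        return min(overlaps, key=lambda p: p.gap_bp) if overlaps else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"Upstream": p.upstream, "Downstream": p.downstream,
             "Gap_bp": p.gap_bp} for p in self.pairs
        ])


def adjacency_report(ann: MitoAnnotation) -> AdjacencyReport:
    """Gap/overlap between consecutive features around the circle.

    For consecutive features by start (wrapping last back to first),
    ``gap_bp = start(next) - end(prev) - 1`` under modular arithmetic, so an
    overlap of k bp is reported as ``-k`` (the printed overlap length
    ``end(prev) - start(next) + 1``).
    """
    feats = sorted(ann.features, key=lambda f: (f.start, f.end))
    if len(feats) < 2:
        raise AnnotationError("adjacency report needs at least two features")
    L = ann.genome_length
    pairs = []
    for prev, nxt in zip(feats, feats[1:] + feats[:1]):
        raw = nxt.start - prev.end - 1
        if nxt is feats[0]:  # wrap pair
            raw += L
        pairs.append(Adjacency(prev.name, nxt.name, raw))
    return AdjacencyReport(tuple(pairs))
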