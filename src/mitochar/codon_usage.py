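"""Codon extraction, start/stop identification, codon counting and RSCU.

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial): AGA/AGG encode Ser (an eight-member Ser family), UGA encodes
Trp, and AUA encodes Met. Relative synonymous codon usage for codon *c* in
synonymous family *F* is

    RSCU(c) = count(c) / (mean count over F),

so values in a family with any usage sum to the family size and a uniformly
used family has RSCU 1 for every member. Stop codons (UAA/UAG under table 5)
are treated as their own two-member family.

Codons are DNA internally; report writers emit the RNA alphabet (U for T).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .annotation_io import AnnotationError, MitoAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticCode",
    "CodonUsageTable",
    "extract_cds",
    "detect_start_stop",
    "count_codons",
    "rscu",
    "codon_usage_report",
    "load_reference_codon_usage",
    "ALL_CODONS",
]

_BASES = "TCAG"
ALL_CODONS = tuple("".join(c) for c in itertools.product(_BASES, repeat=3))


def _dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


def _rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with its synonymous-family partition."""

    code_id: int
    table: Mapping[str, str]            # 64 codons -> aa, stops as '*'
    families: Mapping[str, tuple[str, ...]]  # aa -> member codons

    @classmethod
    def from_ncbi_id(cls, code_id: int = 5) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[code_id]
        table = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            table[stop] = "*"
        assert len(table) == 64
        families: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            families.setdefault(table[codon], []).append(codon)
        return cls(code_id, table,
                   {aa: tuple(cods) for aa, cods in families.items()})

    def translate(self, codon: str) -> str:
        return self.table[_dna(codon)]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == "*"

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.translate(codon)]


INVERTEBRATE_MITO = GeneticCode.from_ncbi_id(5)


@dataclass
class CodonUsageTable:
    """Codon counts, and RSCU once computed."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in ALL_CODONS})
    rscu: Optional[dict[str, float]] = None
    n_skipped: int = 0  # triplets with non-ACGT characters
    zero_families: tuple[str, ...] = ()

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


def extract_cds(ann: MitoAnnotation, gene: str) -> tuple[str, bool]:
    """Reading-sense CDS of a protein-coding gene.

    Returns ``(sequence, frame_ok)`` where ``frame_ok`` is False when the
    annotated length is not a multiple of 3 (possible incomplete stop codon
    or annotation artifact).
    """
    feat = ann.feature(gene)  # KeyError if absent
    if feat.ftype != "PCG":
        raise AnnotationError(f"{gene} is not a protein-coding gene")
    cds = ann.reading_sense(feat)
    frame_ok = len(cds) % 3 == 0
    if not frame_ok:
        logger.warning("%s: CDS length %d not a multiple of 3", gene, len(cds))
    return cds, frame_ok


def detect_start_stop(cds: str,
                      code: GeneticCode = INVERTEBRATE_MITO
                      ) -> tuple[str, str, bool]:
    """Start codon, stop codon (or incomplete-stop marker), completeness.

    The stop is the last complete in-frame triplet when that triplet is a
    stop under the code; otherwise any trailing 1-2 nt are reported as an
    incomplete stop (the ``T``/``TA`` convention, completed by
    polyadenylation in mitochondrial transcripts) and completeness is False.
    """
    cds = _dna(cds)
    if len(cds) < 6:
        raise AnnotationError("CDS shorter than two codons")
    start = cds[:3]
    trailing = len(cds) % 3
    if trailing == 0:
        last = cds[-3:]
        if code.is_stop(last):
            return start, last, True
        return start, f"{last}(no stop)", False
    return start, cds[-trailing:] + "-" * (3 - trailing), False


def count_codons(cds_set: Iterable[str],
                 code: GeneticCode = INVERTEBRATE_MITO,
                 include_stop: bool = True) -> CodonUsageTable:
    """Tally in-frame triplets across a set of CDS strings.

    Trailing partial codons are ignored; triplets with non-ACGT characters
    are skipped and counted in ``n_skipped``. Internal stop triplets are
    tallied unless ``include_stop`` is False — published mitogenome codon
    tables tally every in-frame triplet.
    """
    table = CodonUsageTable()
    for cds in cds_set:
        cds = _dna(cds)
        if len(cds) < 3:
            raise AnnotationError("CDS shorter than one codon")
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            if set(codon) - set("ACGT"):
                table.n_skipped += 1
                continue
            if not include_stop and code.is_stop(codon):
                continue
            table.counts[codon] += 1
    if table.n_skipped:
        logger.info("count_codons: skipped %d ambiguous triplets",
                    table.n_skipped)
    return table


def rscu(table: CodonUsageTable,
         code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsageTable:
    """Attach RSCU values to a codon-usage table.

    Families with zero total usage get RSCU 0 for all members and are
    flagged in ``zero_families``.
    """
    values: dict[str, float] = {}
    zero: list[str] = []
    for aa, members in code.families.items():
        total = sum(table.counts[c] for c in members)
        if total == 0:
            for c in members:
                values[c] = 0.0
            zero.append(aa)
            continue
        mean = total / len(members)
        for c in members:
            values[c] = table.counts[c] / mean
    table.rscu = values
    table.zero_families = tuple(zero)
    return table


def codon_usage_report(table: CodonUsageTable,
                       code: GeneticCode = INVERTEBRATE_MITO,
                       per_thousand: bool = False,
                       ndigits: int = 2) -> pd.DataFrame:
    """Codon table in the published shape (RNA alphabet, RSCU at 2 dp)."""
    if table.rscu is None:
        table = rscu(table, code)
    total = table.total_codons
    rows = []
    for codon in ALL_CODONS:
        row = {
            "Codon": _rna(codon),
            "AA": code.translate(codon),
            "Count": table.counts[codon],
            "RSCU": round(table.rscu[codon], ndigits),
        }
        if per_thousand:
            row["CDspT"] = round(1000.0 * table.counts[codon] / total, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def genome_codon_usage(ann: MitoAnnotation,
                       code: GeneticCode = INVERTEBRATE_MITO,
                       include_stop: bool = True) -> CodonUsageTable:
    """Codon usage across all protein-coding genes of an annotation."""
    pcgs = ann.features_of_type("PCG")
    if not pcgs:
        raise AnnotationError("annotation has no protein-coding genes")
    cds_set = [extract_cds(ann, f.name)[0] for f in pcgs]
    return rscu(count_codons(cds_set, code, include_stop=include_stop), code)


def load_reference_codon_usage() -> pd.DataFrame:
    """Published codon counts and printed RSCU for the reference mitogenome."""
    from .annotation_io import _DATA_DIR

    return pd.read_csv(_DATA_DIR / "ensirostris_codon_usage.tsv",
                       sep="\t", comment="#")
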