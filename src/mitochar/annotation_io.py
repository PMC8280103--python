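"""Reading and writing annotated mitogenomes.

The internal model is a :class:`MitoAnnotation`: a circular genome length, an
ordered list of :class:`GeneFeature` records (1-based inclusive coordinates,
as in GenBank flat files and published organization tables), and optionally
the heavy-strand nucleotide sequence. Gene names are canonicalized to the
37-gene mitochondrial vocabulary (13 protein-coding genes, 22 tRNAs, 2 rRNAs)
plus ``CR`` for the control region.

Features may wrap the circular origin, in which case ``end < start`` and the
length is computed modularly. Duplicated genes carry occurrence suffixes
(``trnQ#2``) so that downstream gene-order analysis can represent
duplications.
"""

from __future__ import annotations

import io
import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeature",
    "MitoAnnotation",
    "AnnotationError",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "GENE_VOCABULARY",
    "canonicalize_gene_name",
    "parse_genbank",
    "parse_feature_table",
    "write_annotation_table",
    "write_genbank",
    "reverse_complement",
    "load_reference_annotation",
]


class AnnotationError(ValueError):
    """Raised for malformed annotations or unparseable input."""


PCG_NAMES = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)
TRNA_NAMES = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnQ", "trnE", "trnG", "trnH",
    "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP", "trnS1",
    "trnS2", "trnT", "trnW", "trnY", "trnV",
)
RRNA_NAMES = ("rrnL", "rrnS")
GENE_VOCABULARY = PCG_NAMES + TRNA_NAMES + RRNA_NAMES + ("CR",)

# amino-acid single/three-letter codes for tRNA names; Leu and Ser are split
# into the two isoacceptor classes (L1 = CUN, L2 = UUR; S1 = AGN, S2 = UCN)
_AA_TO_TRNA = {
    "ala": "trnA", "arg": "trnR", "asn": "trnN", "asp": "trnD",
    "cys": "trnC", "gln": "trnQ", "glu": "trnE", "gly": "trnG",
    "his": "trnH", "ile": "trnI", "lys": "trnK", "met": "trnM",
    "phe": "trnF", "pro": "trnP", "thr": "trnT", "trp": "trnW",
    "tyr": "trnY", "val": "trnV",
    "leu1": "trnL1", "leu2": "trnL2", "ser1": "trnS1", "ser2": "trnS2",
    "l1": "trnL1", "l2": "trnL2", "s1": "trnS1", "s2": "trnS2",
}

_SYNONYMS = {
    "co1": "cox1", "coi": "cox1", "cox1": "cox1", "coxi": "cox1",
    "co2": "cox2", "coii": "cox2", "cox2": "cox2", "coxii": "cox2",
    "co3": "cox3", "coiii": "cox3", "cox3": "cox3", "coxiii": "cox3",
    "cytb": "cob", "cob": "cob", "cytochromeb": "cob",
    "nd1": "nad1", "nad1": "nad1", "nd2": "nad2", "nad2": "nad2",
    "nd3": "nad3", "nad3": "nad3", "nd4": "nad4", "nad4": "nad4",
    "nd4l": "nad4l", "nad4l": "nad4l", "nd5": "nad5", "nad5": "nad5",
    "nd6": "nad6", "nad6": "nad6",
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "16s": "rrnL", "16srrna": "rrnL", "rrnl": "rrnL", "lrrna": "rrnL",
    "lsu": "rrnL", "rrn16": "rrnL",
    "12s": "rrnS", "12srrna": "rrnS", "rrns": "rrnS", "srrna": "rrnS",
    "ssu": "rrnS", "rrn12": "rrnS",
    "dloop": "CR", "controlregion": "CR", "cr": "CR", "atrichregion": "CR",
    "putativecontrolregion": "CR",
}

# codon groups distinguishing the duplicated-isotype tRNAs
_LEU_UUR = {"uur", "uua", "uug", "taa", "tag"}  # anticodon TAA reads UUR
_LEU_CUN = {"cun", "cua", "cuc", "cug", "cuu", "tag_cun"}
_SER_UCN = {"ucn", "uca", "ucc", "ucg", "ucu", "tga"}
_SER_AGN = {"agn", "aga", "agc", "agg", "agu", "tct", "gct"}


def canonicalize_gene_name(raw: str) -> tuple[str, bool]:
    """Map a raw gene/product label to its canonical token.

    Returns ``(token, recognized)``. Unknown labels are returned unchanged
    with ``recognized=False``; they are never dropped. The mapping is
    case-insensitive and idempotent: canonical tokens map to themselves.
    """
    name = raw.strip()
    # occurrence suffix for duplicated genes survives canonicalization
    suffix = ""
    if "#" in name:
        name, _, occ = name.partition("#")
        suffix = "#" + occ
    base, ok = _canonicalize_base(name.strip())
    return base + suffix, ok


def _canonicalize_base(name: str) -> tuple[str, bool]:
    if name in GENE_VOCABULARY:
        return name, True
    squeezed = re.sub(r"[\s_\-\.]+", "", name).lower()
    if squeezed in _SYNONYMS:
        return _SYNONYMS[squeezed], True
    # exact canonical token, case-insensitive (trnl2 -> trnL2)
    lowered = {t.lower(): t for t in GENE_VOCABULARY}
    if squeezed in lowered:
        return lowered[squeezed], True
    # tRNA labels: trnX, tRNA-Xxx, tRNA-Leu(UUR), Leu2, trnL(CUN) ...
    m = re.match(r"^(?:trn|trna)?([a-z]{1,3}[12]?)(?:\(([a-z]{3})\))?$", squeezed)
    if m:
        aa, codon = m.group(1), m.group(2)
        token = _resolve_trna(aa, codon)
        if token is not None:
            return token, True
    return name, False


def _resolve_trna(aa: str, codon: Optional[str]) -> Optional[str]:
    if aa in ("l", "leu", "s", "ser"):
        if codon:
            if codon in _LEU_UUR and aa in ("l", "leu"):
                return "trnL2"
            if codon in _LEU_CUN and aa in ("l", "leu"):
                return "trnL1"
            if codon in _SER_UCN and aa in ("s", "ser"):
                return "trnS2"
            if codon in _SER_AGN and aa in ("s", "ser"):
                return "trnS1"
        return None  # ambiguous without an isotype number or codon
    if aa in _AA_TO_TRNA:
        return _AA_TO_TRNA[aa]
    # single-letter amino-acid code (possibly numbered: L1, S2)
    single = {
        "a": "trnA", "r": "trnR", "n": "trnN", "d": "trnD", "c": "trnC",
        "q": "trnQ", "e": "trnE", "g": "trnG", "h": "trnH", "i": "trnI",
        "k": "trnK", "m": "trnM", "f": "trnF", "p": "trnP", "t": "trnT",
        "w": "trnW", "y": "trnY", "v": "trnV",
        "l1": "trnL1", "l2": "trnL2", "s1": "trnS1", "s2": "trnS2",
    }
    return single.get(aa)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the circular mitogenome.

    Coordinates are 1-based inclusive; ``end < start`` only for features that
    wrap the circular origin.
    """

    name: str
    ftype: str  # PCG | tRNA | rRNA | CR | other
    strand: int  # +1 heavy, -1 light
    start: int
    end: int
    anticodon: Optional[str] = None
    recognized: bool = True

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise AnnotationError(f"strand must be +1/-1, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(
                f"{self.name}: coordinates must be >= 1 "
                f"({self.start}-{self.end})"
            )
        if self.anticodon is not None and self.ftype != "tRNA":
            raise AnnotationError(f"{self.name}: anticodon on non-tRNA feature")

    @property
    def base_name(self) -> str:
        """Name without a duplication occurrence suffix."""
        return self.name.partition("#")[0]

    def length(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    @property
    def wraps(self) -> bool:
        return self.end < self.start


_FTYPE_BY_NAME = {
    **{n: "PCG" for n in PCG_NAMES},
    **{n: "tRNA" for n in TRNA_NAMES},
    **{n: "rRNA" for n in RRNA_NAMES},
    "CR": "CR",
}


def infer_ftype(name: str) -> str:
    return _FTYPE_BY_NAME.get(name.partition("#")[0], "other")


@dataclass
class MitoAnnotation:
    """A circular mitogenome annotation, optionally with sequence."""

    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    sequence: Optional[str] = None
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise AnnotationError("genome_length must be positive")
        for f in self.features:
            if f.start > self.genome_length or f.end > self.genome_length:
                raise AnnotationError(
                    f"{f.name}: coordinates {f.start}-{f.end} outside "
                    f"[1, {self.genome_length}]"
                )
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.genome_length:
                raise AnnotationError(
                    f"sequence length {len(self.sequence)} != genome_length "
                    f"{self.genome_length}"
                )
            if set(self.sequence) - set("ACGTN"):
                raise AnnotationError("sequence has characters outside ACGTN")
        self.features.sort(key=lambda f: (f.start, f.end))
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise AnnotationError(
                f"duplicate feature names without occurrence suffix: {dupes}"
            )

    # -- lookups ---------------------------------------------------------
    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name or f.base_name == name:
                return f
        raise KeyError(name)

    def features_of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    @property
    def genes(self) -> list[GeneFeature]:
        """All features counted as genes (everything except CR/other)."""
        return [f for f in self.features if f.ftype in ("PCG", "tRNA", "rRNA")]

    # -- sequence access -------------------------------------------------
    def heavy_slice(self, feat: GeneFeature) -> str:
        """Heavy-strand sequence of a feature (handles origin wrap)."""
        if self.sequence is None:
            raise AnnotationError("annotation carries no sequence")
        if not feat.wraps:
            return self.sequence[feat.start - 1 : feat.end]
        return self.sequence[feat.start - 1 :] + self.sequence[: feat.end]

    def reading_sense(self, feat: GeneFeature) -> str:
        """Feature sequence in its transcriptional reading sense."""
        s = self.heavy_slice(feat)
        return s if feat.strand == 1 else reverse_complement(s)


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GB_FTYPES = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
              "D-loop": "CR", "misc_feature": None}


def parse_genbank(path: Union[str, Path, io.TextIOBase]) -> MitoAnnotation:
    """Read a GenBank flat file into a :class:`MitoAnnotation`.

    Feature names are canonicalized from the ``gene``/``product``/``note``
    qualifiers; features whose label cannot be canonicalized are retained
    verbatim with a warning and an inferred type.
    """
    try:
        record: SeqRecord = SeqIO.read(path, "genbank")
    except Exception as exc:  # pragma: no cover - Biopython error detail
        raise AnnotationError(f"unparseable GenBank file: {exc}") from exc
    length = len(record.seq)
    circular = record.annotations.get("topology", "circular") == "circular"
    sequence = str(record.seq).upper() if len(record.seq) else None

    features: list[GeneFeature] = []
    seen: dict[str, int] = {}
    for gbf in record.features:
        if gbf.type not in _GB_FTYPES:
            continue
        raw = _feature_label(gbf)
        if raw is None:
            continue
        name, ok = canonicalize_gene_name(raw)
        ftype = _GB_FTYPES[gbf.type] or infer_ftype(name)
        if ftype is None or ftype == "other":
            ftype = infer_ftype(name)
        if not ok:
            warnings.warn(f"unrecognized gene label {raw!r}; kept verbatim")
            if ftype == "other" and gbf.type in ("CDS", "tRNA", "rRNA"):
                ftype = _GB_FTYPES[gbf.type]
        start, end, strand = _location_bounds(gbf.location, length)
        anticodon = None
        if ftype == "tRNA":
            ac = gbf.qualifiers.get("anticodon") or gbf.qualifiers.get("note")
            if ac:
                m = re.search(r"[ACGTUacgtu]{3}", ac[0].split(":")[-1])
                if m:
                    anticodon = m.group(0).upper().replace("U", "T")
        seen[name] = seen.get(name, 0) + 1
        if seen[name] > 1:
            name = f"{name}#{seen[name]}"
        features.append(GeneFeature(name, ftype, strand, start, end,
                                    anticodon=anticodon, recognized=ok))
    return MitoAnnotation(length, features, circular=circular,
                          sequence=sequence, accession=record.id or None)


def _feature_label(gbf: SeqFeature) -> Optional[str]:
    for key in ("gene", "product", "note", "standard_name"):
        if key in gbf.qualifiers:
            return str(gbf.qualifiers[key][0])
    if gbf.type == "D-loop":
        return "CR"
    return None


def _location_bounds(loc, length: int) -> tuple[int, int, int]:
    strand = -1 if loc.strand == -1 else 1
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-wrapping join(a..L,1..b)
        if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == length:
            return int(parts[1].start) + 1, int(parts[0].end), strand
        return int(parts[0].start) + 1, int(parts[-1].end), strand
    return int(loc.start) + 1, int(loc.end), strand


def write_genbank(ann: MitoAnnotation, path: Union[str, Path]) -> None:
    """Write the annotation (with sequence) as a GenBank flat file."""
    if ann.sequence is None:
        raise AnnotationError("GenBank output requires a sequence")
    record = SeqRecord(
        Seq(ann.sequence),
        id=ann.accession or "SYNTHETIC",
        name=(ann.accession or "SYNTHETIC")[:16],
        description="synthetic mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if ann.circular else "linear",
        },
    )
    type_by_ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                     "CR": "D-loop", "other": "misc_feature"}
    for f in ann.features:
        strand = f.strand
        if not f.wraps:
            loc = FeatureLocation(f.start - 1, f.end, strand=strand)
        else:
            loc = CompoundLocation([
                FeatureLocation(f.start - 1, ann.genome_length, strand=strand),
                FeatureLocation(0, f.end, strand=strand),
            ])
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        record.features.append(SeqFeature(loc, type=type_by_ftype[f.ftype],
                                          qualifiers=quals))
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# Plain feature table (the machine form of a published organization table)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["Gene", "Direction", "Start", "End", "Length",
                  "Anticodon", "Start codon", "Stop codon"]


def parse_feature_table(
    source: Union[str, Path, io.TextIOBase],
    genome_length: Optional[int] = None,
    sequence: Optional[str] = None,
) -> MitoAnnotation:
    """Read a delimited Gene/Direction/Start/End table.

    ``genome_length`` may alternatively be declared in a header comment of
    the form ``# genome_length=16350 circular=true``.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    circular = True
    for line in text.splitlines():
        if line.startswith("#"):
            m = re.search(r"genome_length\s*=\s*(\d+)", line)
            if m and genome_length is None:
                genome_length = int(m.group(1))
            m = re.search(r"circular\s*=\s*(\w+)", line)
            if m:
                circular = m.group(1).lower() in ("true", "1", "yes")
    if genome_length is None:
        raise AnnotationError(
            "genome_length not given and no '# genome_length=' header found"
        )

    rows = [ln for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
    if not rows:
        raise AnnotationError("empty feature table")
    delim = "\t" if "\t" in rows[0] else ","
    header = [c.strip() for c in rows[0].split(delim)]
    idx = {c.lower(): i for i, c in enumerate(header)}
    for needed in ("gene", "direction", "start", "end"):
        if needed not in idx:
            raise AnnotationError(f"feature table missing column {needed!r}")

    features: list[GeneFeature] = []
    seen: dict[str, int] = {}
    for ln in rows[1:]:
        cells = [c.strip() for c in ln.split(delim)]
        name_raw = cells[idx["gene"]]
        direction = cells[idx["direction"]]
        start = int(cells[idx["start"]].replace(",", ""))
        end = int(cells[idx["end"]].replace(",", ""))
        if not (1 <= start <= genome_length and 1 <= end <= genome_length):
            raise AnnotationError(
                f"{name_raw}: coordinates {start}-{end} outside "
                f"[1, {genome_length}]"
            )
        name, ok = canonicalize_gene_name(name_raw)
        strand = -1 if direction in ("-", "−", "L", "light") else 1
        anticodon = None
        if "anticodon" in idx and len(cells) > idx["anticodon"]:
            val = cells[idx["anticodon"]]
            if val and val not in ("-", ""):
                anticodon = val.upper().replace("U", "T")
        ftype = infer_ftype(name)
        if anticodon is not None and ftype != "tRNA":
            anticodon = None
        seen[name] = seen.get(name, 0) + 1
        if seen[name] > 1:
            name = f"{name}#{seen[name]}"
        features.append(GeneFeature(name, ftype, strand, start, end,
                                    anticodon=anticodon, recognized=ok))
    return MitoAnnotation(genome_length, features, circular=circular,
                          sequence=sequence)


def write_annotation_table(ann: MitoAnnotation,
                           path: Union[str, Path, io.TextIOBase]) -> None:
    """Write the annotation as a TSV organization table.

    Start/stop codon columns are filled only when the annotation carries a
    sequence; ``parse_feature_table(write(x))`` reproduces ``x``'s features.
    """
    from .codon_usage import detect_start_stop  # local import, no cycle at load

    lines = [
        "# genome_length=%d circular=%s"
        % (ann.genome_length, "true" if ann.circular else "false"),
        "\t".join(_TABLE_COLUMNS),
    ]
    for f in ann.features:
        start_codon = stop_codon = "-"
        if f.ftype == "PCG" and ann.sequence is not None:
            cds = ann.reading_sense(f)
            if len(cds) >= 6:
                start_codon, stop_codon, _ = detect_start_stop(cds)
        lines.append("\t".join([
            f.name,
            "+" if f.strand == 1 else "-",
            str(f.start),
            str(f.end),
            str(f.length(ann.genome_length)),
            f.anticodon or "-",
            start_codon,
            stop_codon,
        ]))
    text = "\n".join(lines) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


_DATA_DIR = Path(__file__).parent / "data"


def load_reference_annotation() -> MitoAnnotation:
    """The bundled Exhippolysmata ensirostris annotation (GenBank MK681888)."""
    return parse_feature_table(_DATA_DIR / "ensirostris_features.tsv")
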