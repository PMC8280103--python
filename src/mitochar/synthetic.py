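"""Synthetic mitogenomes and codon-level sequence evolution.

The generator emulates the structures the characterization pipeline assumes:
a circular ~16 kb genome carrying the 37-gene ancestral decapod order plus a
control region, configurable heavy-strand base composition (hence AT/GC
content and skews), protein-coding genes that are clean open reading frames
under the invertebrate mitochondrial code, and optional rearrangement
operations applied to the template gene order.

Sequence pairs and species panels with a controlled dN/dS ratio are produced
by codon-level acceptance-rejection: single-nucleotide changes are proposed
uniformly, changes creating a stop codon are rejected, synonymous changes
are always accepted and nonsynonymous changes are accepted with probability
``omega``. In the low-divergence regime the Nei-Gojobori estimate of Ka/Ks
recovers ``omega``.

All randomness flows from a single integer seed via
:class:`numpy.random.Generator`; equal specs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .annotation_io import (
    AnnotationError,
    GeneFeature,
    MitoAnnotation,
    PCG_NAMES,
    RRNA_NAMES,
    TRNA_NAMES,
    infer_ftype,
    reverse_complement,
)
from .codon_usage import ALL_CODONS, GeneticCode, INVERTEBRATE_MITO
from .gene_order import GeneOrder, load_named_orders

__all__ = [
    "GenomeSpec",
    "EvolutionSpec",
    "generate_genome",
    "evolve_pair",
    "generate_panel",
    "DEFAULT_GENE_LENGTHS",
    "DEFAULT_COMPOSITION",
]

# Heavy-strand base composition of the study system (A, T, G, C percent).
DEFAULT_COMPOSITION = {"A": 32.51, "T": 31.91, "G": 14.24, "C": 21.33}

# Per-gene lengths (bp) modeled on the reference mitogenome, PCGs rounded to
# complete codons. tRNAs 63-70 bp, rRNAs ~1.4 kb/0.8 kb, CR ~1.2 kb.
DEFAULT_GENE_LENGTHS = {
    "cox1": 1512, "cox2": 687, "cox3": 783, "cob": 1137, "atp6": 666,
    "atp8": 165, "nad1": 870, "nad2": 981, "nad3": 366, "nad4": 1227,
    "nad4l": 255, "nad5": 1704, "nad6": 498,
    "rrnL": 1368, "rrnS": 818, "CR": 1249,
    "trnA": 63, "trnR": 64, "trnN": 65, "trnD": 63, "trnC": 65, "trnQ": 68,
    "trnE": 69, "trnG": 67, "trnH": 64, "trnI": 67, "trnL1": 67, "trnL2": 66,
    "trnK": 68, "trnM": 67, "trnF": 64, "trnP": 63, "trnS1": 68, "trnS2": 70,
    "trnT": 63, "trnW": 66, "trnY": 65, "trnV": 64,
}

_ANTICODONS = {
    "trnA": "GCA", "trnR": "CGA", "trnN": "AAC", "trnD": "GAC",
    "trnC": "TGC", "trnQ": "CAA", "trnE": "GAA", "trnG": "GGA",
    "trnH": "CAC", "trnI": "ATC", "trnL1": "CTA", "trnL2": "TTA",
    "trnK": "AAA", "trnM": "ATG", "trnF": "TTC", "trnP": "CCA",
    "trnS1": "AGA", "trnS2": "TCA", "trnT": "ACA", "trnW": "TGA",
    "trnY": "TAC", "trnV": "GTA",
}

RearrangementOp = tuple  # ("translocate"|"invert"|"duplicate", gene, anchor)


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic mitogenome.

    ``composition`` is the heavy-strand A/T/G/C target in percent (must sum
    to 100). ``codon_weights`` optionally fixes the codon-usage distribution
    of protein-coding genes (64 weights keyed by DNA codon; stops are used
    only as terminators) — by default codons are drawn position-wise from
    the base composition, which keeps genome-wide composition on target.
    ``ops`` are applied to the template order before layout.
    """

    seed: int = 0
    genome_length: Optional[int] = None    # None: sum of parts
    order_template: str = "ancestral_decapoda"
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    gene_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    codon_weights: Optional[Mapping[str, float]] = None
    ops: tuple[RearrangementOp, ...] = ()
    spacer: int = 2                        # default intergenic gap (bp)
    code_id: int = 5

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        # printed composition tables carry rounding; renormalized at draw time
        if abs(total - 100.0) > 0.05:
            raise AnnotationError(
                f"composition must sum to 100, got {total}")


def _resolve_template(spec: GenomeSpec) -> GeneOrder:
    named = load_named_orders()
    if spec.order_template in named:
        return named[spec.order_template]
    return GeneOrder.from_string(spec.order_template)


def _apply_ops(order: GeneOrder, ops: Sequence[RearrangementOp]) -> GeneOrder:
    for op in ops:
        kind, gene = op[0], op[1]
        anchor = op[2] if len(op) > 2 else None
        if kind == "translocate":
            order = order.translocate(gene, anchor)
        elif kind == "invert":
            order = order.invert(gene)
        elif kind == "duplicate":
            order = order.duplicate(gene, anchor)
        else:
            raise AnnotationError(f"unknown rearrangement op {kind!r}")
    return order


def _base_probs(composition: Mapping[str, float]) -> np.ndarray:
    p = np.array([composition[b] for b in "ACGT"], dtype=float)
    return p / p.sum()


def _draw_bases(rng: np.random.Generator, n: int,
                probs: np.ndarray) -> str:
    idx = rng.choice(4, size=n, p=probs)
    return "".join("ACGT"[i] for i in idx)


def _sense_codon_distribution(spec: GenomeSpec,
                              code: GeneticCode
                              ) -> tuple[list[str], np.ndarray]:
    """Distribution over non-stop codons for internal CDS positions."""
    if spec.codon_weights is not None:
        items = [(c.upper().replace("U", "T"), float(w))
                 for c, w in spec.codon_weights.items() if float(w) > 0]
        items = [(c, w) for c, w in items if not code.is_stop(c)]
        codons = [c for c, _ in items]
        weights = np.array([w for _, w in items], dtype=float)
        return codons, weights / weights.sum()
    # Position-independent base draw, raked so that the codon marginals hit
    # the target base composition despite the exclusion of stop codons
    # (which would otherwise deplete A+T in coding regions).
    probs = _base_probs(spec.composition)
    codons = [c for c in ALL_CODONS if not code.is_stop(c)]
    base_index = {b: i for i, b in enumerate("ACGT")}
    comp = np.array([[sum(1 for x in c if x == b) / 3.0 for b in "ACGT"]
                     for c in codons])
    factors = probs.copy()
    for _ in range(200):
        weights = np.array([factors[base_index[c[0]]]
                            * factors[base_index[c[1]]]
                            * factors[base_index[c[2]]] for c in codons])
        weights /= weights.sum()
        marginal = weights @ comp
        if np.max(np.abs(marginal - probs)) < 1e-12:
            break
        factors *= probs / marginal
    return codons, weights / weights.sum()


def _draw_cds(rng: np.random.Generator, length: int,
              codons: Sequence[str], probs: np.ndarray,
              code: GeneticCode) -> str:
    """An open reading frame of ``length`` bp: ATG/ATA start, internal
    sense codons from the distribution, TAA stop."""
    if length % 3 or length < 9:
        raise AnnotationError(
            f"PCG length must be a multiple of 3 and >= 9, got {length}")
    n_internal = length // 3 - 2
    start = "ATG" if rng.random() < 0.7 else "ATA"
    internal = rng.choice(len(codons), size=n_internal, p=probs)
    stop = "TAA" if rng.random() < 0.8 else "TAG"
    return start + "".join(codons[i] for i in internal) + stop


def generate_genome(spec: GenomeSpec) -> MitoAnnotation:
    """Generate a circular annotated mitogenome from a spec.

    Features are laid out in template order starting at position
    ``spacer + 1`` (the origin falls inside a spacer, as in real
    annotations); protein-coding genes are stop-free ORFs in reading sense.
    Raises when the requested ``genome_length`` cannot hold the parts.
    """
    rng = np.random.default_rng(spec.seed)
    code = GeneticCode.from_ncbi_id(spec.code_id)
    order = _apply_ops(_resolve_template(spec), spec.ops).normalized()
    probs = _base_probs(spec.composition)
    sense_codons, sense_probs = _sense_codon_distribution(spec, code)

    lengths = {}
    for name, _ in order.tokens:
        base = name.partition("#")[0]
        if base not in spec.gene_lengths:
            raise AnnotationError(f"no length configured for {name}")
        lengths[name] = int(spec.gene_lengths[base])

    minimal = sum(lengths.values()) + spec.spacer * len(order)
    if spec.genome_length is None:
        genome_length = minimal
        slack = 0
    else:
        genome_length = int(spec.genome_length)
        slack = genome_length - minimal
        if slack < 0:
            raise AnnotationError(
                f"genome_length {genome_length} cannot hold "
                f"{minimal} bp of features and spacers")

    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 0  # 0-based cursor on the heavy strand

    def emit_spacer(n: int) -> None:
        nonlocal pos
        if n > 0:
            chunks.append(_draw_bases(rng, n, probs))
            pos += n

    # distribute slack into the spacer upstream of the first feature, which
    # models an expanded AT-rich region without touching gene lengths
    emit_spacer(spec.spacer + slack)
    for name, sign in order.tokens:
        base = name.partition("#")[0]
        ftype = infer_ftype(base)
        length = lengths[name]
        if ftype == "PCG":
            reading = _draw_cds(rng, length, sense_codons, sense_probs, code)
            heavy = reading if sign > 0 else reverse_complement(reading)
        else:
            heavy = _draw_bases(rng, length, probs)
        start = pos + 1
        end = pos + length
        chunks.append(heavy)
        pos += length
        features.append(GeneFeature(
            name, ftype, sign, start, end,
            anticodon=_ANTICODONS.get(base) if ftype == "tRNA" else None))
        if name != order.tokens[-1][0]:
            emit_spacer(spec.spacer)
    # trailing spacer closes the circle back to position 1
    remaining = genome_length - pos
    emit_spacer(remaining)
    sequence = "".join(chunks)
    assert len(sequence) == genome_length
    return MitoAnnotation(genome_length, features, circular=True,
                          sequence=sequence, accession="SYNTHETIC")


# ---------------------------------------------------------------------------
# Codon-level evolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionSpec:
    """Parameters of one simulated CDS pair (or one star-panel branch)."""

    n_codons: int = 500
    subs_per_codon: float = 0.3   # expected accepted substitutions per codon
    omega: float = 0.2            # acceptance probability of nonsyn changes
    code_id: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


def _draw_ancestor(rng: np.random.Generator, spec: EvolutionSpec,
                   code: GeneticCode) -> list[str]:
    sense = [c for c in ALL_CODONS if not code.is_stop(c)]
    idx = rng.choice(len(sense), size=spec.n_codons)
    return [sense[i] for i in idx]


def _evolve(rng: np.random.Generator, codons: list[str],
            spec: EvolutionSpec, code: GeneticCode) -> list[str]:
    """Apply a Poisson number of accepted substitutions to a codon list."""
    codons = list(codons)
    target = rng.poisson(spec.subs_per_codon * spec.n_codons)
    accepted = 0
    while accepted < target:
        i = int(rng.integers(len(codons)))
        pos = int(rng.integers(3))
        cur = codons[i]
        alt = "ACGT"[int(rng.integers(4))]
        if alt == cur[pos]:
            continue
        mutant = cur[:pos] + alt + cur[pos + 1:]
        if code.is_stop(mutant):
            continue  # lethal; proposal discarded
        if code.translate(mutant) != code.translate(cur):
            if rng.random() >= spec.omega:
                continue  # nonsynonymous change rejected by selection
        codons[i] = mutant
        accepted += 1
    return codons


def evolve_pair(spec: EvolutionSpec) -> tuple[str, str]:
    """(ancestor, descendant) aligned CDS pair under the spec's omega."""
    rng = np.random.default_rng(spec.seed)
    code = GeneticCode.from_ncbi_id(spec.code_id)
    ancestor = _draw_ancestor(rng, spec, code)
    descendant = _evolve(rng, ancestor, spec, code)
    return "".join(ancestor), "".join(descendant)


def generate_panel(genes: Union[int, Sequence[str]],
                   species: Union[int, Sequence[str]],
                   omegas: Sequence[float],
                   seed: int = 0,
                   n_codons: int = 300,
                   subs_per_codon: float = 0.2,
                   code_id: int = 5) -> dict[str, dict[str, str]]:
    """Star-topology CDS panels: one ancestor per gene, each species an
    independently evolved descendant with the gene's omega.

    Returns {gene: {species: CDS}} suitable for
    :func:`mitochar.kaks.panel_kaks`.
    """
    gene_names = ([f"gene{i+1}" for i in range(genes)]
                  if isinstance(genes, int) else list(genes))
    species_names = ([f"sp{i+1}" for i in range(species)]
                     if isinstance(species, int) else list(species))
    if len(omegas) != len(gene_names):
        raise ValueError("need one omega per gene")
    root = np.random.default_rng(seed)
    code = GeneticCode.from_ncbi_id(code_id)
    panel: dict[str, dict[str, str]] = {}
    for gene, omega in zip(gene_names, omegas):
        spec = EvolutionSpec(n_codons=n_codons,
                             subs_per_codon=subs_per_codon,
                             omega=omega, code_id=code_id,
                             seed=int(root.integers(2**31)))
        rng = np.random.default_rng(spec.seed)
        ancestor = _draw_ancestor(rng, spec, code)
        panel[gene] = {
            sp: "".join(_evolve(rng, ancestor, spec, code))
            for sp in species_names
        }
    return panel
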