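"""Pairwise Ka/Ks by the Nei-Gojobori (1986) counting method.

For each codon, every position contributes a fractional synonymous site
``f = s / v`` where ``s`` is the number of one-step nucleotide changes at
that position that leave the amino acid unchanged and ``v`` the number of
viable one-step changes (changes creating a stop codon are excluded from the
denominator). Synonymous sites ``S`` sum the fractions over the three
positions; nonsynonymous sites are ``N = 3 - S``. Sites are averaged between
the two sequences.

Differences between a codon pair are counted over all minimal mutational
pathways (d! orderings of the d differing positions), each step classified
synonymous or nonsynonymous, pathways weighted equally; pathways passing
through a stop codon are excluded when at least one stop-free pathway
exists, otherwise all pathways are averaged and the pair is flagged.

Proportions ``pS = Sd/S`` and ``pN = Nd/N`` are corrected for multiple hits
with the Jukes-Cantor formula ``K = -(3/4) ln(1 - 4p/3)``; ``omega = Ka/Ks``
estimates the dN/dS ratio, with values well below one indicating purifying
selection.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .codon_usage import GeneticCode, INVERTEBRATE_MITO

logger = logging.getLogger(__name__)

__all__ = [
    "KaKsResult",
    "SaturationError",
    "codon_sites",
    "codon_path_differences",
    "ng86",
    "panel_kaks",
    "read_alignment_panel",
    "jukes_cantor",
]

_BASES = "ACGT"


class SaturationError(ValueError):
    """Raised when a substitution proportion reaches the JC limit p >= 3/4."""


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction K = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"substitution proportion {p:.3f} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def _sites_cached(codon: str, code_id: int) -> tuple[float, float]:
    code = GeneticCode.from_ncbi_id(code_id)
    aa = code.translate(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site decomposition")
    s_total = 0.0
    for pos in range(3):
        syn = viable = 0
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if code.is_stop(mutant):
                continue  # stop mutations excluded from the denominator
            viable += 1
            if code.translate(mutant) == aa:
                syn += 1
        if viable:
            s_total += syn / viable
    return s_total, 3.0 - s_total


def codon_sites(codon: str,
                code: GeneticCode = INVERTEBRATE_MITO) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon."""
    return _sites_cached(codon.upper().replace("U", "T"), code.code_id)


@lru_cache(maxsize=None)
def _paths_cached(a: str, b: str, code_id: int
                  ) -> tuple[float, float, bool]:
    code = GeneticCode.from_ncbi_id(code_id)
    if code.is_stop(a) or code.is_stop(b):
        raise ValueError("pathway counting requires non-stop codons")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0, True
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        stop_free = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if code.is_stop(nxt) and nxt != b:
                stop_free = False
            if code.translate(cur) == code.translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if stop_free:
            valid.append((sd, nd))
    paths = valid if valid else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd, bool(valid)


def codon_path_differences(codon_a: str, codon_b: str,
                           code: GeneticCode = INVERTEBRATE_MITO
                           ) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts."""
    a = codon_a.upper().replace("U", "T")
    b = codon_b.upper().replace("U", "T")
    sd, nd, stop_free = _paths_cached(a, b, code.code_id)
    if not stop_free:
        logger.warning("no stop-free pathway between %s and %s; "
                       "averaged over all pathways", a, b)
    return sd, nd


@dataclass(frozen=True)
class KaKsResult:
    """NG86 estimates for one aligned CDS pair."""

    gene: Optional[str]
    pair: tuple[str, str]
    n_codons: int          # codon pairs actually compared
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: Optional[float]    # None on saturation
    Ka: Optional[float]
    ratio: Optional[float]  # None when Ks == 0 or saturated
    n_skipped: int = 0      # codon pairs skipped (ambiguity/gaps/stops)

    @property
    def undefined(self) -> bool:
        return self.ratio is None


def ng86(cds_a: str, cds_b: str,
         code: GeneticCode = INVERTEBRATE_MITO,
         gene: Optional[str] = None,
         pair: tuple[str, str] = ("A", "B")) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for two aligned, equal-length CDS strings.

    Codon pairs containing gaps, ambiguity characters or stop codons are
    skipped pairwise. Sequence order does not affect the result.
    """
    a = cds_a.upper().replace("U", "T")
    b = cds_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError("aligned length is not a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_codons = n_skipped = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if (set(ca) | set(cb)) - set(_BASES):
            n_skipped += 1
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            n_skipped += 1
            continue
        sa, na = codon_sites(ca, code)
        sb, nb = codon_sites(cb, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = codon_path_differences(ca, cb, code)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codon pairs")
    pS, pN = Sd / S, Nd / N
    try:
        Ks: Optional[float] = jukes_cantor(pS)
    except SaturationError:
        Ks = None
    try:
        Ka: Optional[float] = jukes_cantor(pN)
    except SaturationError:
        Ka = None
    if Ks is None or Ka is None or Ks == 0.0:
        ratio = None
    else:
        ratio = Ka / Ks
    return KaKsResult(gene, pair, n_codons, S, N, Sd, Nd, pS, pN,
                      Ks, Ka, ratio, n_skipped=n_skipped)


def panel_kaks(genes: Mapping[str, Mapping[str, str]],
               focal: Optional[str] = None,
               code: GeneticCode = INVERTEBRATE_MITO) -> pd.DataFrame:
    """Per-gene average Ka, Ks and Ka/Ks across a species panel.

    ``genes`` maps gene name -> {species: aligned CDS}. With ``focal`` set,
    only focal-vs-other pairs are compared; otherwise all pairs. Pairs with
    an undefined ratio are excluded from the ratio mean and counted.
    Per-gene failures (e.g. length mismatches) are logged and skipped so the
    panel completes.
    """
    rows = []
    for gene, panel in genes.items():
        species = list(panel)
        if len(species) < 2:
            logger.warning("%s: fewer than two species; skipped", gene)
            continue
        if focal is not None:
            pairs = [(focal, s) for s in species if s != focal]
        else:
            pairs = list(itertools.combinations(species, 2))
        results: list[KaKsResult] = []
        try:
            for sp1, sp2 in pairs:
                results.append(ng86(panel[sp1], panel[sp2], code,
                                    gene=gene, pair=(sp1, sp2)))
        except ValueError as exc:
            logger.warning("%s: %s; gene skipped", gene, exc)
            continue
        defined = [r.ratio for r in results if r.ratio is not None]
        ka = [r.Ka for r in results if r.Ka is not None]
        ks = [r.Ks for r in results if r.Ks is not None]
        rows.append({
            "Gene": gene,
            "Ka": sum(ka) / len(ka) if ka else float("nan"),
            "Ks": sum(ks) / len(ks) if ks else float("nan"),
            "Ka/Ks": (sum(defined) / len(defined) if defined
                      else float("nan")),
            "n_pairs": len(results),
            "n_undefined": len(results) - len(defined),
        })
        if len(defined) < len(results):
            logger.info("%s: %d pair(s) with undefined Ka/Ks excluded",
                        gene, len(results) - len(defined))
    return pd.DataFrame(rows)


def read_alignment_panel(directory: Union[str, Path],
                         pattern: str = "*.fa*"
                         ) -> dict[str, dict[str, str]]:
    """Read per-gene aligned FASTA files (one record per species).

    The gene name is the file stem; record ids are species labels.
    """
    panel: dict[str, dict[str, str]] = {}
    for path in sorted(Path(directory).glob(pattern)):
        records = {rec.id: str(rec.seq).upper()
                   for rec in SeqIO.parse(str(path), "fasta")}
        if records:
            panel[path.stem] = records
    if not panel:
        raise FileNotFoundError(f"no FASTA panels under {directory}")
    return panel
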