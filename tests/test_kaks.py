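"""Nei-Gojobori site/pathway counting against literal brute-force oracles,
and parameter recovery on simulated pairs and panels."""

import itertools
import math
import random

import numpy as np
import pytest

from mitochar.codon_usage import ALL_CODONS, INVERTEBRATE_MITO
from mitochar.kaks import (
    SaturationError,
    codon_path_differences,
    codon_sites,
    jukes_cantor,
    ng86,
    panel_kaks,
)
from mitochar.synthetic import EvolutionSpec, evolve_pair, generate_panel

from tests_oracle_helpers import oracle_ng86, oracle_paths, oracle_sites

CODE = INVERTEBRATE_MITO
SENSE = [c for c in ALL_CODONS if not CODE.is_stop(c)]


class TestCodonSites:
    def test_fourfold_third_position(self):
        for codon in CODE.families["G"]:  # GGN glycine box
            s, n = codon_sites(codon)
            assert s >= 1.0  # third position fully synonymous
            assert s + n == pytest.approx(3.0)

    def test_no_synonymous_neighbors(self):
        # under table 5 TGG (Trp) has its one synonymous partner TGA one
        # step away, but e.g. AAT/AAC asparagine has exactly 1/3 at pos 3;
        # a codon with zero synonymous one-step neighbours:
        zero = [c for c in SENSE if codon_sites(c)[0] == 0.0]
        for c in zero:
            for pos in range(3):
                for alt in "ACGT":
                    if alt == c[pos]:
                        continue
                    mut = c[:pos] + alt + c[pos + 1:]
                    if CODE.table[mut] != "*":
                        assert CODE.table[mut] != CODE.table[c]

    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE:
            assert codon_sites(codon) == pytest.approx(oracle_sites(codon),
                                                       abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_sites("TAA")


class TestPathDifferences:
    def test_identical_codons(self):
        assert codon_path_differences("ATG", "ATG") == (0.0, 0.0)

    def test_single_synonymous_change(self):
        assert codon_path_differences("GGA", "GGC") == (1.0, 0.0)

    def test_all_pairs_match_oracle(self):
        for a, b in itertools.product(SENSE, repeat=2):
            got = codon_path_differences(a, b)
            want = oracle_paths(a, b)
            assert got == pytest.approx(want, abs=1e-12), (a, b)
            # pathway-averaged counts sum to the Hamming distance
            ham = sum(x != y for x, y in zip(a, b))
            assert got[0] + got[1] == pytest.approx(ham)


class TestNg86:
    def test_identical_sequences(self):
        a = "ATGAAACCCGGG"
        r = ng86(a, a)
        assert r.Ka == 0.0 and r.Ks == 0.0 and r.ratio is None

    def test_symmetry(self):
        rng = random.Random(5)
        a = "".join(rng.choice(SENSE) for _ in range(50))
        b = "".join(rng.choice(SENSE) for _ in range(50))
        r1, r2 = ng86(a, b), ng86(b, a)
        assert r1.Ka == pytest.approx(r2.Ka)
        assert r1.Ks == pytest.approx(r2.Ks)

    def test_site_conservation(self):
        rng = random.Random(9)
        a = "".join(rng.choice(SENSE) for _ in range(120))
        b = "".join(rng.choice(SENSE) for _ in range(120))
        r = ng86(a, b)
        assert r.S_sites + r.N_sites == pytest.approx(3 * r.n_codons)

    def test_small_pairs_match_exhaustive_oracle(self):
        """Random pairs of <= 5 codons agree with a literal site/pathway
        enumeration to 1e-12."""
        rng = random.Random(1234)
        for _ in range(300):
            n = rng.randint(1, 5)
            a = [rng.choice(SENSE) for _ in range(n)]
            # derive b by limited mutation so divergence stays subsaturated
            b = []
            for codon in a:
                c = codon
                for _ in range(rng.randint(0, 2)):
                    pos = rng.randrange(3)
                    alt = rng.choice("ACGT")
                    mut = c[:pos] + alt + c[pos + 1:]
                    if CODE.table[mut] != "*":
                        c = mut
                b.append(c)
            sa, sb = "".join(a), "".join(b)
            r = ng86(sa, sb)
            if r.Ka is None or r.Ks is None:
                continue
            ka, ks = oracle_ng86(sa, sb)
            assert r.Ka == pytest.approx(ka, abs=1e-12)
            assert r.Ks == pytest.approx(ks, abs=1e-12)

    def test_saturation_raises_in_jc(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)

    def test_gapped_codons_skipped(self):
        r = ng86("ATG---AAA", "ATGCCCAAA")
        assert r.n_codons == 2 and r.n_skipped == 1


class TestOmegaRecovery:
    def test_purifying_omega_recovered(self):
        a, b = evolve_pair(EvolutionSpec(n_codons=2000, omega=0.2, seed=42))
        r = ng86(a, b)
        assert r.ratio == pytest.approx(0.2, abs=0.05)

    def test_neutral_limit(self):
        a, b = evolve_pair(EvolutionSpec(n_codons=2000, omega=1.0, seed=42))
        r = ng86(a, b)
        assert r.ratio == pytest.approx(1.0, abs=0.1)

    def test_omega_zero_gives_negligible_ka(self):
        # strictly zero nonsynonymous acceptance; residual Ka comes only
        # from pathway averaging over multiply-hit codons
        a, b = evolve_pair(EvolutionSpec(n_codons=1000, omega=0.0, seed=7))
        r = ng86(a, b)
        assert r.Ka < 1e-3
        assert r.Ks > 0.1

    def test_monotonic_in_omega(self):
        """Estimated Ka/Ks increases with the generating omega
        (regression slope across seeds strictly positive)."""
        omegas, estimates = [], []
        for omega in (0.1, 0.3, 0.5, 0.7, 0.9):
            for seed in (1, 2, 3):
                a, b = evolve_pair(EvolutionSpec(
                    n_codons=600, omega=omega, seed=seed))
                r = ng86(a, b)
                omegas.append(omega)
                estimates.append(r.ratio)
        slope = np.polyfit(omegas, estimates, 1)[0]
        assert slope > 0


class TestPanel:
    def test_identical_panel_flagged_undefined(self):
        cds = "ATGAAACCCGGGTTA"
        frame = panel_kaks({"cox1": {"sp1": cds, "sp2": cds, "sp3": cds}})
        row = frame.iloc[0]
        assert row.n_undefined == row.n_pairs == 3
        assert math.isnan(row["Ka/Ks"])

    def test_two_species_reduces_to_pairwise(self):
        a, b = evolve_pair(EvolutionSpec(n_codons=300, omega=0.4, seed=8))
        frame = panel_kaks({"g": {"A": a, "B": b}})
        direct = ng86(a, b)
        assert frame.iloc[0]["Ka/Ks"] == pytest.approx(direct.ratio)
        assert frame.iloc[0].n_pairs == 1

    def test_rank_order_recovered(self):
        panel = generate_panel(3, 6, [0.2, 0.5, 0.9], seed=7,
                               n_codons=400)
        frame = panel_kaks(panel).set_index("Gene")
        est = [frame.loc[f"gene{i}", "Ka/Ks"] for i in (1, 2, 3)]
        assert est[0] < est[1] < est[2]

    def test_purifying_panel_all_below_one(self):
        omegas = [0.2, 0.4, 0.6]
        panel = generate_panel(3, 5, omegas, seed=21, n_codons=400)
        frame = panel_kaks(panel)
        assert (frame["Ka/Ks"] < 1).all()

    def test_length_mismatch_skips_gene_not_panel(self):
        a, b = evolve_pair(EvolutionSpec(n_codons=100, omega=0.5, seed=3))
        genes = {
            "good": {"A": a, "B": b},
            "bad": {"A": a, "B": a[:-3]},
        }
        frame = panel_kaks(genes)
        assert list(frame.Gene) == ["good"]
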