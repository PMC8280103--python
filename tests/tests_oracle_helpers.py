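"""Naive, loop-literal oracles shared by the test modules.

These deliberately re-derive the quantities with the most direct possible
enumeration and stay independent of the package's optimized code paths.
"""

import itertools
import math

from mitochar.codon_usage import ALL_CODONS, INVERTEBRATE_MITO

CODE = INVERTEBRATE_MITO
SENSE = [c for c in ALL_CODONS if CODE.table[c] != "*"]


def oracle_sites(codon):
    s = 0.0
    for pos in range(3):
        syn, viable = 0, 0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if CODE.table[mut] == "*":
                continue
            viable += 1
            if CODE.table[mut] == CODE.table[codon]:
                syn += 1
        if viable:
            s += syn / viable
    return s, 3 - s


def oracle_paths(a, b):
    diff = [i for i in range(3) if a[i] != b[i]]
    paths, clean = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if CODE.table[nxt] == "*" and nxt != b:
                ok = False
            if CODE.table[cur] == CODE.table[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd))
        if ok:
            clean.append((sd, nd))
    use = clean or paths
    return (sum(p[0] for p in use) / len(use),
            sum(p[1] for p in use) / len(use))


def oracle_ng86(a, b):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = oracle_paths(ca, cb)
        Sd += sd
        Nd += nd
    pS, pN = Sd / S, Nd / N
    ks = -0.75 * math.log(1 - 4 * pS / 3)
    ka = -0.75 * math.log(1 - 4 * pN / 3)
    return ka, ks


def random_small_pair(rng, max_codons=5):
    n = rng.randint(1, max_codons)
    a = [rng.choice(SENSE) for _ in range(n)]
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
    return "".join(a), "".join(b)


def brute_tdrl(derived_names, ref_names):
    """Enumerate every per-gene copy-loss pattern of a tandem duplication."""
    doubled = ref_names + ref_names
    n = len(ref_names)
    for keep in itertools.product((0, 1), repeat=n):
        result = []
        for j, g in enumerate(doubled):
            i = j % n
            if (j < n) == (keep[i] == 0):
                result.append(g)
        if tuple(result) == tuple(derived_names):
            return True
    return False
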