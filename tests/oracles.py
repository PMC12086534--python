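"""Independent brute-force oracles for isotope and labeling math.

These deliberately avoid the package's convolution code path: per-element
distributions come from closed-form multinomial enumeration over heavy-isotope
placements, elements and label states are combined with explicit Python
double loops, and a second oracle enumerates every per-atom isotope
assignment with itertools.product for tiny formulas.
"""
from itertools import product as iproduct
from math import comb, prod


def element_shift_dist(count, pattern, K):
    """Shift distribution of `count` atoms of one element, shifts 0..K.

    `pattern` is a list of (shift, abundance) with shift 0 first.  Exact for
    the retained shifts: configurations heavier than K cannot contribute.
    """
    light = dict(pattern)[0]
    heavy = [(s, a) for s, a in pattern if s > 0]
    dist = [0.0] * (K + 1)
    ranges = [range(0, min(count, K // s) + 1) for s, _ in heavy]
    for ks in iproduct(*ranges):
        atoms = sum(ks)
        shift = sum(k * s for k, (s, _) in zip(ks, heavy))
        if atoms > count or shift > K:
            continue
        coeff, rem = 1, count
        for k in ks:
            coeff *= comb(rem, k)
            rem -= k
        dist[shift] += (coeff * light ** (count - atoms)
                        * prod(a ** k for k, (_, a) in zip(ks, heavy)))
    return dist


def combine(a, b, K):
    """Distribution of summed shifts, explicit double loop."""
    out = [0.0] * (K + 1)
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            if i + j <= K:
                out[i + j] += ai * bj
    return out


def enumeration_natural_mid(counts, patterns, K):
    """Natural-abundance MID of a formula by multinomial enumeration.

    `counts`: element -> atom count; `patterns`: element -> [(shift, abund)].
    Returns the m0..mK fractions (not including the truncated tail).
    """
    total = [1.0] + [0.0] * K
    for el, c in counts.items():
        total = combine(total, element_shift_dist(c, patterns[el], K), K)
    return total


def atom_product_mid(counts, patterns, K):
    """Natural MID by exhaustive per-atom state enumeration (tiny formulas only)."""
    atoms = []
    for el, c in counts.items():
        atoms.extend([patterns[el]] * c)
    dist = [0.0] * (K + 1)
    for states in iproduct(*atoms):
        shift = sum(s for s, _ in states)
        if shift <= K:
            dist[shift] += prod(a for _, a in states)
    return dist


def binom_pmf(j, n, p):
    return comb(n, j) * p**j * (1.0 - p) ** (n - j)


def enumeration_forward_mid(counts, patterns, K, f, p, n):
    """Observed MID under the labeling model, by enumeration.

    Every atom (exchangeable hydrogens included) sits at natural abundance;
    a fraction f of molecules additionally carries j ~ Binomial(n, p) excess
    labels at the exchangeable positions.
    """
    nat = enumeration_natural_mid(counts, patterns, K)
    mix = [binom_pmf(j, n, p) * f for j in range(K + 1)]
    mix[0] += 1.0 - f
    return combine(nat, mix, K)
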