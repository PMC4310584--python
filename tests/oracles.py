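"""Independent brute-force reference implementations used only by tests.

Each function is coded directly from the primary definitions (exact rational
arithmetic where possible, naive loops elsewhere) and deliberately shares no
code with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_exact_oracle(n_aa_hom: int, n_het: int, n_bb_hom: int) -> Fraction:
    """Exact two-sided HWE p-value by full rational enumeration."""
    n = n_aa_hom + n_het + n_bb_hom
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n_bb_hom + n_het
    if n_a == 0 or n_b == 0:
        return Fraction(1)

    def prob(h: int) -> Fraction:
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        # multinomial over genotypes divided by allele-count multinomial
        num = Fraction(2**h) * Fraction(
            factorial(n), factorial(a)
        ) / (factorial(h) * factorial(b))
        den = Fraction(factorial(2 * n)) / (
            factorial(n_a) * factorial(n_b)
        )
        return num / den

    rare = min(n_a, n_b)
    probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
    obs = probs[n_het]
    return sum(p for p in probs.values() if p <= obs)


def nei_he_oracle(genotypes: list[int]) -> float:
    """Unbiased expected heterozygosity from a dosage list (no missing)."""
    n = len(genotypes)
    p = sum(genotypes) / (2 * n)
    return (2 * n / (2 * n - 1)) * (1 - p**2 - (1 - p) ** 2)


def wc84_theta_oracle(
    counts1: tuple[int, int, int], counts2: tuple[int, int, int]
) -> tuple[float, float, float]:
    """WC84 (a, b, c) for one locus from genotype count triples.

    Transcribed equation-by-equation from the 1984 estimator for r samples
    (here r = 2), written as explicit loops over samples.
    """
    r = 2
    samples = [counts1, counts2]
    n_i = [sum(cts) for cts in samples]
    p_i = [(2 * cts[2] + cts[1]) / (2 * n) for cts, n in zip(samples, n_i)]
    h_i = [cts[1] / n for cts, n in zip(samples, n_i)]

    nbar = sum(n_i) / r
    c2 = sum((n - nbar) ** 2 for n in n_i) / ((r - 1) * nbar**2)  # unused check
    nc = (r * nbar - sum(n**2 for n in n_i) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    ssq = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)

    a = (nbar / nc) * (
        ssq - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * ssq - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * ssq - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc84_fis_oracle(counts_per_locus: list[tuple[int, int, int]]) -> float:
    """WC84 single-population f-hat as a ratio of sums over loci."""
    num = 0.0
    den = 0.0
    for n0, n1, n2 in counts_per_locus:
        n = n0 + n1 + n2
        p = (2 * n2 + n1) / (2 * n)
        h = n1 / n
        b = (n / (n - 1)) * (p * (1 - p) - ((2 * n - 1) / (4 * n)) * h)
        c = h / 2
        num += b
        den += b + c
    return num / den


def local_linear_oracle(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, h: float
) -> np.ndarray:
    """Local-linear Gaussian-kernel regression by per-point weighted LSQ."""
    out = np.empty(len(grid))
    for i, g in enumerate(grid):
        w = np.exp(-0.5 * ((x - g) / h) ** 2)
        X = np.column_stack([np.ones_like(x), x - g])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        out[i] = beta[0]
    return out


def haplotype_counts_phase_known(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Direct gamete counts when no double heterozygote exists."""
    counts = np.zeros(4)  # AB, Ab, aB, ab with A/B = alt
    for a, b in zip(g1, g2):
        assert not (a == 1 and b == 1), "phase unknown"
        al1 = [1] * a + [0] * (2 - a)
        al2 = [1] * b + [0] * (2 - b)
        for x, yv in zip(al1, al2):
            counts[(1 - x) * 2 + (1 - yv)] += 1
    return counts / counts.sum()


def theta_h_oracle(he: float) -> float:
    return 0.5 * ((1.0 / (1.0 - he)) ** 2 - 1.0)
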