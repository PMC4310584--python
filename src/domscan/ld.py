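"""Pairwise linkage disequilibrium and Hill-Weir decay fitting.

Two-locus haplotype frequencies for unphased diploid genotypes come from an
EM algorithm (double heterozygotes are split between the coupling and
repulsion phases at each iteration). From the converged frequencies,
``D = p_AB - p_A p_B``, ``D' = |D| / D_max``, and
``r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B))``.

The decay of r^2 with genetic distance follows the Hill & Weir (1988)
expectation under drift-recombination balance,

    E[r^2] = (10+C) / ((2+C)(11+C))
             * [1 + ((3+C)(12+12C+C^2)) / (n (2+C)(11+C))],

with C = rho * d (d in cM) and n the number of sampled chromosomes. rho is
fitted by nonlinear least squares; the half-decay distance is the genetic
distance at which the fitted curve drops to half of its value at distance
zero (the curve never reaches zero - its large-distance floor is 1/n - so
"half of the initial signal" is the well-defined notion).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize

from .datamodel import MISSING, GenotypePanel, LinkageMap


def em_haplotype_freqs(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, int]:
    """EM haplotype frequencies (p_AB, p_Ab, p_aB, p_ab) for two loci.

    ``g1``/``g2`` are alternate-allele dosages in {0,1,2, MISSING}; only
    individuals called at both loci contribute. With no double
    heterozygotes the frequencies equal direct gamete counts.
    """
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[ok].astype(int), g2[ok].astype(int)
    n = len(g1)
    if n < 2:
        raise ValueError("need >= 2 jointly called individuals")
    table = np.zeros((3, 3))
    np.add.at(table, (g1, g2), 1)

    # known gamete contributions (counting the alt allele as 'A'/'B')
    # genotype pair (i, j): i copies of alt at locus 1, j at locus 2
    known = np.zeros(4)  # AB, Ab, aB, ab with A/B = alt alleles
    for i in range(3):
        for j in range(3):
            c = table[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            # at most one locus is heterozygous, so the gamete pair is
            # unique: [alt]*i + [ref]*(2-i) zipped across the two loci
            al1 = [1] * i + [0] * (2 - i)
            al2 = [1] * j + [0] * (2 - j)
            for a, b in zip(al1, al2):
                known[(1 - a) * 2 + (1 - b)] += c
    # index map: 0 = AB(alt,alt), 1 = Ab, 2 = aB, 3 = ab
    # (1-a)*2+(1-b): a=1,b=1 -> 0; a=1,b=0 -> 1; a=0,b=1 -> 2; a=0,b=0 -> 3

    n_dh = table[1, 1]
    total = 2.0 * n
    freqs = np.full(4, 0.25)
    # initialize from allele frequencies (linkage equilibrium)
    pA = (2 * table[2, :].sum() + table[1, :].sum()) / total
    pB = (2 * table[:, 2].sum() + table[:, 1].sum()) / total
    freqs = np.array(
        [pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)]
    )
    freqs = np.clip(freqs, 1e-12, None)
    freqs /= freqs.sum()
    it = 0
    for it in range(1, max_iter + 1):
        coupling = freqs[0] * freqs[3]
        repulsion = freqs[1] * freqs[2]
        denom = coupling + repulsion
        if denom <= 0:
            frac = 0.5
        else:
            frac = coupling / denom
        counts = known.copy()
        counts[0] += n_dh * frac
        counts[3] += n_dh * frac
        counts[1] += n_dh * (1 - frac)
        counts[2] += n_dh * (1 - frac)
        new = counts / total
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new
    return freqs, it


def ld_from_freqs(freqs: np.ndarray) -> tuple[float, float]:
    """(r^2, D') from haplotype frequencies (p_AB, p_Ab, p_aB, p_ab)."""
    p_ab, p_aB, p_Ab, p_AB = freqs[3], freqs[2], freqs[1], freqs[0]
    pA = p_AB + p_Ab
    pB = p_AB + p_aB
    d = p_AB - pA * pB
    var = pA * (1 - pA) * pB * (1 - pB)
    if var <= 0:
        raise ValueError("monomorphic locus: LD undefined")
    r2 = d * d / var
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    return float(r2), float(dprime)


def pairwise_ld(
    panel: GenotypePanel,
    lmap: LinkageMap,
    max_distance: float = 50.0,
    min_joint: int = 2,
) -> pd.DataFrame:
    """All within-linkage-group locus pairs up to ``max_distance`` cM apart.

    ``panel`` must hold a single population. Pairs with a locus monomorphic
    in the population (no LD defined) or with fewer than ``min_joint``
    jointly called individuals are skipped.
    """
    if len(panel.populations) != 1:
        raise ValueError("pairwise_ld expects a single-population panel")
    geno = panel.genotypes
    idx_of = {lid: j for j, lid in enumerate(panel.locus_ids)}
    rows = []
    for lg in lmap.linkage_groups():
        in_lg = lmap.frame[lmap.frame["linkage_group"] == lg]
        loci = [lid for lid in in_lg.index if lid in idx_of]
        positions = {lid: float(in_lg.loc[lid, "position_cm"]) for lid in loci}
        for la, lb in combinations(loci, 2):
            dist = abs(positions[la] - positions[lb])
            if dist > max_distance:
                continue
            g1, g2 = geno[:, idx_of[la]], geno[:, idx_of[lb]]
            ok = (g1 != MISSING) & (g2 != MISSING)
            if ok.sum() < min_joint:
                continue
            try:
                freqs, _ = em_haplotype_freqs(g1, g2)
                r2, dprime = ld_from_freqs(freqs)
            except ValueError:
                continue
            rows.append(
                {
                    "locus_a": la,
                    "locus_b": lb,
                    "linkage_group": lg,
                    "distance_cm": dist,
                    "r2": r2,
                    "dprime": dprime,
                    "n_haplotypes": int(2 * ok.sum()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_a",
            "locus_b",
            "linkage_group",
            "distance_cm",
            "r2",
            "dprime",
            "n_haplotypes",
        ],
    )


def ld_matrix(pairs: pd.DataFrame, loci: list[str], stat: str = "r2") -> pd.DataFrame:
    """Square per-linkage-group matrix (heat-map input) from the pair table."""
    mat = pd.DataFrame(np.nan, index=loci, columns=loci)
    for _, row in pairs.iterrows():
        a, b = row["locus_a"], row["locus_b"]
        if a in mat.index and b in mat.index:
            mat.loc[a, b] = mat.loc[b, a] = row[stat]
    np.fill_diagonal(mat.values, 1.0)
    return mat


def hill_weir_expected_r2(c: np.ndarray, n_chromosomes: int) -> np.ndarray:
    """Hill-Weir drift-recombination expectation of r^2 at scaled distance C."""
    c = np.asarray(c, dtype=float)
    n = float(n_chromosomes)
    lead = (10.0 + c) / ((2.0 + c) * (11.0 + c))
    corr = 1.0 + ((3.0 + c) * (12.0 + 12.0 * c + c * c)) / (
        n * (2.0 + c) * (11.0 + c)
    )
    return lead * corr


@dataclass
class DecayFit:
    rho_per_cm: float
    n_chromosomes: int
    half_decay: float
    rss: float


def fit_decay(pairs: pd.DataFrame, n_chromosomes: int) -> DecayFit:
    """Fit rho in C = rho * distance by least squares and locate half-decay.

    Requires at least 10 pairs spanning at least two distinct distances, and
    some variation in r^2 (a constant signal carries no decay information).
    """
    d = pairs["distance_cm"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    if len(d) < 10:
        raise ValueError("need >= 10 pairs to fit the decay curve")
    if len(np.unique(d)) < 2:
        raise ValueError("all pairs at one distance: rho unidentifiable")
    if np.ptp(r2) == 0:
        raise ValueError("constant r2: no decay signal to fit")

    def model(dist, rho):
        return hill_weir_expected_r2(rho * dist, n_chromosomes)

    pos_d = d[d > 0]
    p0 = 1.0 / np.median(pos_d) if len(pos_d) else 1.0
    popt, _ = optimize.curve_fit(
        model, d, r2, p0=[p0], bounds=(1e-12, np.inf), maxfev=10_000
    )
    rho = float(popt[0])
    rss = float(np.sum((model(d, rho) - r2) ** 2))

    f0 = float(hill_weir_expected_r2(0.0, n_chromosomes))
    target = f0 / 2.0
    floor = 1.0 / n_chromosomes
    if target <= floor:
        raise ValueError("half of the initial LD lies below the 1/n floor")

    def g(dist):
        return float(hill_weir_expected_r2(rho * dist, n_chromosomes)) - target

    hi = 1.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e9:
            raise ValueError("half-decay distance out of range")
    half = float(optimize.brentq(g, 0.0, hi, xtol=1e-10, rtol=1e-12))
    return DecayFit(
        rho_per_cm=rho, n_chromosomes=n_chromosomes, half_decay=half, rss=rss
    )
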