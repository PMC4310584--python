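"""Diversity and differentiation statistics for a wild/hatchery pair.

Implements Nei's (1987) unbiased heterozygosities, Weir & Cockerham's (1984)
variance-component estimators of FIS and FST (theta-hat, with bootstrap
confidence intervals over loci), the Weir & Hill (2002) population-specific
FST in its allele-matching (beta) form, the standardized log heterozygosity
ratio LnRH of Kauer et al. (2003), and the moment formulas used to interpret
pair-level results (Ne = t/(2 FST), proportional diversity loss, and the
marker count needed to tile a map at the LD half-decay scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import GenotypePanel


# ----------------------------------------------------------------------
# per-population summaries
# ----------------------------------------------------------------------
def _pop_arrays(panel: GenotypePanel, label: str):
    """Per-locus (n, het count, alt allele frequency) for one population."""
    n0, n1, n2, n = panel.dosage_counts(label)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, (n1 + 2 * n2) / (2 * np.maximum(n, 1)), np.nan)
    return n, n1, p


def het_stats(panel: GenotypePanel) -> pd.DataFrame:
    """Per-locus Ho, unbiased He and MAF for each population.

    He uses Nei's small-sample correction ``(2n/(2n-1)) (1 - p^2 - q^2)``
    with n the number of genotyped individuals at the locus. Loci with no
    genotyped individuals in a population get NaN entries.
    """
    blocks = {}
    for label in panel.populations:
        n, n_het, p = _pop_arrays(panel, label)
        with np.errstate(divide="ignore", invalid="ignore"):
            ho = np.where(n > 0, n_het / np.maximum(n, 1), np.nan)
            raw = 1.0 - p**2 - (1.0 - p) ** 2
            he = np.where(n > 0, 2 * n / np.maximum(2 * n - 1, 1) * raw, np.nan)
            maf = np.minimum(p, 1.0 - p)
        blocks[label] = pd.DataFrame(
            {"n": n, "Ho": ho, "He": he, "MAF": maf},
            index=pd.Index(panel.locus_ids, name="locus_id"),
        )
    return pd.concat(blocks, axis=1)


# ----------------------------------------------------------------------
# Weir & Cockerham (1984)
# ----------------------------------------------------------------------
def wc_components(n1, p1, h1, n2, p2, h2):
    """WC84 variance components (a, b, c) for two samples, vectorized.

    ``n``: genotyped individuals, ``p``: allele frequency, ``h``: observed
    heterozygote proportion, per locus per sample. A locus monomorphic in
    the pooled pair yields (0, 0, 0).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    # loci unobserved in a sample propagate NaN; callers mask on a+b+c
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (
            nbar
            / nc
            * (s2 - 1.0 / (nbar - 1.0) * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0))
        )
        b = (
            nbar
            / (nbar - 1.0)
            * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        )
        c = hbar / 2.0
    return a, b, c


def _bootstrap_ratio(
    num: np.ndarray, den: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """95% percentile interval for a ratio-of-sums over resampled loci."""
    n = len(num)
    idx = rng.integers(0, n, size=(n_boot, n))
    num_s = num[idx].sum(axis=1)
    den_s = den[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        thetas = num_s / den_s
    thetas = thetas[np.isfinite(thetas)]
    lo, hi = np.percentile(thetas, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class FstResult:
    per_locus: pd.DataFrame  # columns a, b, c, theta
    theta: float
    ci: tuple[float, float]


def wc_fst(
    panel: GenotypePanel,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> FstResult:
    """Weir-Cockerham theta-hat between the panel's two populations.

    Multilocus theta is the ratio of sums ``sum(a) / sum(a+b+c)`` over loci
    with non-zero denominator; the CI comes from percentile bootstrap over
    loci (``n_boot`` replicates, seeded).
    """
    pops = panel.populations
    if len(pops) != 2:
        raise ValueError("wc_fst requires exactly two populations")
    (n1, h1c, p1), (n2, h2c, p2) = (_pop_arrays(panel, lab) for lab in pops)
    with np.errstate(divide="ignore", invalid="ignore"):
        h1 = np.where(n1 > 0, h1c / np.maximum(n1, 1), np.nan)
        h2 = np.where(n2 > 0, h2c / np.maximum(n2, 1), np.nan)
    a, b, c = wc_components(n1, p1, h1, n2, p2, h2)
    den = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_locus = np.where(den != 0, a / den, np.nan)
    per_locus = pd.DataFrame(
        {"a": a, "b": b, "c": c, "theta": theta_locus},
        index=pd.Index(panel.locus_ids, name="locus_id"),
    )
    usable = np.isfinite(den) & (den != 0)
    if not usable.any():
        raise ValueError("no locus with defined WC84 components")
    theta = float(a[usable].sum() / den[usable].sum())
    rng = np.random.default_rng(seed)
    ci = _bootstrap_ratio(a[usable], den[usable], n_boot, rng)
    return FstResult(per_locus=per_locus, theta=theta, ci=ci)


@dataclass
class FisResult:
    f: float
    ci: tuple[float, float]


def wc_fis(
    panel: GenotypePanel,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> dict[str, FisResult]:
    """Per-population WC84 small-sample FIS (f-hat) with bootstrap CIs.

    f-hat is the ratio of sums ``sum(b) / sum(b+c)`` of the within-population
    components over loci; -1 for a fully heterozygous population, ~0 under
    Hardy-Weinberg proportions.
    """
    out = {}
    for label in panel.populations:
        n, n_het, p = _pop_arrays(panel, label)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(n > 0, n_het / np.maximum(n, 1), np.nan)
            b = (
                n
                / np.maximum(n - 1.0, 1e-300)
                * (p * (1.0 - p) - (2.0 * n - 1.0) / (4.0 * n) * h)
            )
        c = h / 2.0
        den = b + c
        usable = np.isfinite(den) & (den != 0) & (n > 1)
        if not usable.any():
            raise ValueError(f"no usable locus for FIS in population {label!r}")
        f = float(b[usable].sum() / den[usable].sum())
        rng = np.random.default_rng(seed)
        ci = _bootstrap_ratio(b[usable], den[usable], n_boot, rng)
        out[label] = FisResult(f=f, ci=ci)
    return out


# ----------------------------------------------------------------------
# Weir & Hill (2002) population-specific FST, matching-proportion form
# ----------------------------------------------------------------------
def pop_specific_fst(panel: GenotypePanel) -> dict[str, float]:
    """Population-specific FST (beta_i) via allele-matching proportions.

    ``M_i`` is the unbiased probability that two distinct alleles drawn from
    population i match (1 minus unbiased gene diversity); ``M_B`` the
    probability that one allele from each population matches. Each beta is a
    ratio of sums over loci: ``sum(M_i - M_B) / sum(1 - M_B)``. Negative
    values mean the population is closer to the pool than average.
    """
    pops = panel.populations
    if len(pops) != 2:
        raise ValueError("pop_specific_fst requires exactly two populations")
    hs = het_stats(panel)
    he = {lab: hs[(lab, "He")].to_numpy() for lab in pops}
    p = {}
    for lab in pops:
        _, _, freq = _pop_arrays(panel, lab)
        p[lab] = freq
    p1, p2 = p[pops[0]], p[pops[1]]
    m_between = p1 * p2 + (1.0 - p1) * (1.0 - p2)
    usable = np.isfinite(m_between) & np.isfinite(he[pops[0]]) & np.isfinite(he[pops[1]])
    denom = (1.0 - m_between)[usable].sum()
    if denom <= 0:
        raise ValueError("pair monomorphic everywhere: beta undefined")
    out = {}
    for lab in pops:
        m_within = 1.0 - he[lab]
        out[lab] = float((m_within - m_between)[usable].sum() / denom)
    return out


# ----------------------------------------------------------------------
# LnRH (Kauer et al. 2003)
# ----------------------------------------------------------------------
def _theta_h(he: np.ndarray) -> np.ndarray:
    return 0.5 * ((1.0 / (1.0 - he)) ** 2 - 1.0)


@dataclass
class LnRHResult:
    table: pd.DataFrame  # lnrh_raw, lnrh_z
    raw_mean: float
    raw_sd: float


def lnrh(
    panel: GenotypePanel,
    wild_label: str,
    dom_label: str,
) -> LnRHResult:
    """Standardized heterozygosity ratio per locus.

    ``lnrh_raw = ln(theta_H(wild) / theta_H(dom))`` with ``theta_H =
    0.5 [(1/(1-He))^2 - 1]``. Loci monomorphic in one population (He = 0)
    use the floor He = 1/(2n) so sweep candidates stay in the scan. Raw
    values are z-standardized to mean 0, SD 1 over defined loci; the raw
    (mean, SD) pair doubles as the normal-fit diagnostic.
    """
    hs = het_stats(panel)
    out = pd.DataFrame(index=hs.index, columns=["lnrh_raw", "lnrh_z"], dtype=float)
    he_w = hs[(wild_label, "He")].to_numpy().copy()
    he_d = hs[(dom_label, "He")].to_numpy().copy()
    n_w = hs[(wild_label, "n")].to_numpy()
    n_d = hs[(dom_label, "n")].to_numpy()
    if np.any(he_w[np.isfinite(he_w)] >= 1.0) or np.any(he_d[np.isfinite(he_d)] >= 1.0):
        raise ValueError("He = 1 is impossible for a finite biallelic sample")
    floor_w = he_w == 0
    floor_d = he_d == 0
    he_w[floor_w] = 1.0 / (2.0 * n_w[floor_w])
    he_d[floor_d] = 1.0 / (2.0 * n_d[floor_d])
    defined = np.isfinite(he_w) & np.isfinite(he_d) & (n_w > 0) & (n_d > 0)
    raw = np.full(len(out), np.nan)
    raw[defined] = np.log(_theta_h(he_w[defined]) / _theta_h(he_d[defined]))
    mean = float(np.nanmean(raw))
    sd = float(np.nanstd(raw[defined], ddof=1))
    out["lnrh_raw"] = raw
    # a fully flat raw column (every locus identical) has no scale to divide
    out["lnrh_z"] = (raw - mean) / sd if sd > 0 else raw - mean
    return LnRHResult(table=out, raw_mean=mean, raw_sd=sd)


def lnrh_threshold(alpha: float) -> float:
    """Two-sided standard-normal critical value; 0.01 -> 2.5758 (2.58 at 2 dp)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(sps.norm.ppf(1.0 - alpha / 2.0))


def expected_false_positives(n_loci: int, alpha: float) -> int:
    """Loci expected beyond a two-tailed alpha by chance: round(n * alpha)."""
    if n_loci < 0:
        raise ValueError("n_loci must be non-negative")
    return int(math.floor(n_loci * alpha + 0.5))


# ----------------------------------------------------------------------
# moment formulas
# ----------------------------------------------------------------------
def ne_moment(t: float, fst: float) -> float:
    """Moment estimator of effective size from drift: Ne = t / (2 FST)."""
    if fst <= 0:
        raise ValueError("fst must be positive")
    if t <= 0:
        raise ValueError("t must be positive")
    return t / (2.0 * fst)


def diversity_loss(he_wild: float, he_dom: float) -> float:
    """Proportional diversity loss F = (H_wild - H_dom) / H_wild."""
    if he_wild <= 0:
        raise ValueError("wild He must be positive")
    return (he_wild - he_dom) / he_wild


def markers_needed(map_length: float, half_decay: float) -> int:
    """Markers to tile a map at the LD half-decay spacing: floor(L / d)."""
    if half_decay <= 0:
        raise ValueError("half_decay must be positive")
    # guard against binary-float quotients landing just below an integer
    return int(math.floor(map_length / half_decay + 1e-9))


# ----------------------------------------------------------------------
# pair-level assembly
# ----------------------------------------------------------------------
@dataclass
class PairSummary:
    fst: float
    fst_ci: tuple[float, float]
    fis: dict[str, FisResult]
    beta: dict[str, float]
    mean_he: dict[str, float]
    mean_ho: dict[str, float]
    ne_moment: float
    diversity_loss_f: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop in self.fis:
            rows.append(
                {
                    "population": pop,
                    "Ho": self.mean_ho[pop],
                    "He": self.mean_he[pop],
                    "FIS": self.fis[pop].f,
                    "FIS_lo": self.fis[pop].ci[0],
                    "FIS_hi": self.fis[pop].ci[1],
                    "beta": self.beta[pop],
                    "FST": self.fst,
                    "FST_lo": self.fst_ci[0],
                    "FST_hi": self.fst_ci[1],
                    "Ne_moment": self.ne_moment,
                    "diversity_loss_F": self.diversity_loss_f,
                }
            )
        return pd.DataFrame(rows).set_index("population")


def locus_stat_table(
    panel: GenotypePanel,
    wild_label: str,
    dom_label: str,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, FstResult, LnRHResult]:
    """Assemble the per-locus statistics table for the pair.

    Returns the flat table (per-population n/Ho/He/MAF plus the WC
    components and LnRH columns) along with the full FST and LnRH results.
    """
    hs = het_stats(panel)
    fst = wc_fst(panel, n_boot=n_boot, seed=seed)
    ln = lnrh(panel, wild_label, dom_label)
    flat = hs.copy()
    flat.columns = [f"{pop}_{stat}" for pop, stat in flat.columns]
    for col in ("a", "b", "c", "theta"):
        flat[col] = fst.per_locus[col]
    flat["lnrh_raw"] = ln.table["lnrh_raw"]
    flat["lnrh_z"] = ln.table["lnrh_z"]
    return flat, fst, ln


def pair_summary(
    panel: GenotypePanel,
    wild_label: str,
    dom_label: str,
    t: float,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> PairSummary:
    hs = het_stats(panel)
    fst = wc_fst(panel, n_boot=n_boot, seed=seed)
    fis = wc_fis(panel, n_boot=n_boot, seed=seed)
    beta = pop_specific_fst(panel)
    mean_he = {lab: float(np.nanmean(hs[(lab, "He")])) for lab in panel.populations}
    mean_ho = {lab: float(np.nanmean(hs[(lab, "Ho")])) for lab in panel.populations}
    ne = ne_moment(t, fst.theta) if fst.theta > 0 else float("nan")
    return PairSummary(
        fst=fst.theta,
        fst_ci=fst.ci,
        fis=fis,
        beta=beta,
        mean_he=mean_he,
        mean_ho=mean_ho,
        ne_moment=ne,
        diversity_loss_f=diversity_loss(mean_he[wild_label], mean_he[dom_label]),
    )
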