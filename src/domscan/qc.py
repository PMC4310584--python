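"""Ordered SNP quality-control pipeline for a wild/hatchery pair.

Filters are applied per population, in the order of the study's retention
table: (1) loci with more than 30% missing genotypes, (2) loci whose
observed allele-symbol count is not exactly two (all-missing, monomorphic
and putatively duplicated tri-allelic assays), (3) minor allele frequency
below 5%, (4) exact Hardy-Weinberg test p below 0.001 (both heterozygote
deficit and excess). The "common" set is the intersection of the two
populations' survivors; the "mapped" set additionally requires a linkage-map
position. Note the prose order (allele counts first) and the table order
(missingness first) yield the same final sets but different intermediate
counts; the table order is used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING_ALLELE, GenotypePanel, LinkageMap, PairConfig

STAGES = ("input", "missingness", "allele_count", "maf", "hwe")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test for one biallelic locus.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the conditional probabilities of all configurations no
    more probable than the observed one (probability-mass two-sidedness, so
    both heterozygote deficit and excess are detected). Returns 1.0 for a
    monomorphic locus.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if n_A == 0 or n_a == 0:
        return 1.0
    rare = min(n_A, n_a)
    # heterozygote counts share the parity of the rare allele count
    hets = range(rare % 2, rare + 1, 2)
    log_probs = {}
    base = (
        math.lgamma(n + 1)
        + math.lgamma(n_A + 1)
        + math.lgamma(n_a + 1)
        - math.lgamma(2 * n + 1)
    )
    for h in hets:
        a = (n_A - h) // 2
        b = (n_a - h) // 2
        log_probs[h] = (
            base
            + h * math.log(2)
            - math.lgamma(a + 1)
            - math.lgamma(h + 1)
            - math.lgamma(b + 1)
        )
    obs = log_probs[n_Aa]
    tol = 1e-12
    p = sum(math.exp(lp) for lp in log_probs.values() if lp <= obs + tol)
    return min(1.0, p)


@dataclass
class FilterReport:
    """Retention counts after each QC stage, per population and for the pair."""

    per_population: dict[str, dict[str, int]]
    common: int
    mapped: int

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.per_population).T
        frame["common"] = self.common
        frame["mapped"] = self.mapped
        frame.index.name = "population"
        return frame

    def validate(self) -> None:
        for pop, counts in self.per_population.items():
            vals = [counts[s] for s in STAGES]
            if any(b > a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"non-monotone retention counts for {pop}")
        if self.common > min(c["hwe"] for c in self.per_population.values()):
            raise ValueError("common exceeds a population's survivor count")
        if self.mapped > self.common:
            raise ValueError("mapped exceeds common")


@dataclass
class QCResult:
    per_population: dict[str, GenotypePanel]
    common: GenotypePanel
    mapped: GenotypePanel
    report: FilterReport


def _population_survivors(
    panel: GenotypePanel, label: str, cfg: PairConfig
) -> tuple[np.ndarray, dict[str, int]]:
    """Boolean survivor mask over panel loci for one population."""
    sub = panel.alleles[panel.population_labels == label]  # (n_ind, n_loci, 2)
    n_ind = sub.shape[0]
    called = (sub[..., 0] != MISSING_ALLELE) & (sub[..., 1] != MISSING_ALLELE)
    n_called = called.sum(axis=0)

    counts = {"input": panel.n_loci}
    alive = np.ones(panel.n_loci, dtype=bool)

    # (1) strictly more than missing_max missing genotypes; the epsilon keeps
    # an exactly-at-threshold locus (e.g. 9/30) on the retained side
    miss_frac = (n_ind - n_called) / n_ind
    alive &= ~(miss_frac > cfg.missing_max + 1e-9)
    counts["missingness"] = int(alive.sum())

    # (2) observed allele-symbol count within this population must be 2
    n_sym = np.zeros(panel.n_loci, dtype=int)
    symbols: list[np.ndarray] = []
    for j in range(panel.n_loci):
        col = sub[:, j, :]
        uniq = np.unique(col[col != MISSING_ALLELE])
        symbols.append(uniq)
        n_sym[j] = len(uniq)
    alive &= n_sym == 2
    counts["allele_count"] = int(alive.sum())

    # (3) MAF from non-missing calls, strictly below maf_min fails
    maf = np.ones(panel.n_loci)
    for j in np.flatnonzero(alive):
        col = sub[:, j, :]
        c1 = int((col == symbols[j][0]).sum())
        tot = int(2 * n_called[j])
        p = c1 / tot
        maf[j] = min(p, 1.0 - p)
    alive &= ~(maf < cfg.maf_min)
    counts["maf"] = int(alive.sum())

    # (4) exact HWE p strictly below hwe_alpha fails
    if cfg.hwe_alpha > 0:
        for j in np.flatnonzero(alive):
            col = sub[:, j, :]
            ok = called[:, j]
            first = col[ok, 0] == symbols[j][0]
            second = col[ok, 1] == symbols[j][0]
            het = int((first != second).sum())
            hom1 = int((first & second).sum())
            hom2 = int(ok.sum()) - het - hom1
            if hwe_exact_test(hom1, het, hom2) < cfg.hwe_alpha:
                alive[j] = False
    counts["hwe"] = int(alive.sum())
    return alive, counts


def apply_filters(
    panel: GenotypePanel,
    lmap: LinkageMap | None,
    cfg: PairConfig,
) -> QCResult:
    """Run the ordered QC stages and assemble the retention report.

    Returns per-population filtered panels (each restricted to its own
    individuals and survivors), the common panel (both populations, loci
    surviving in both), the mapped panel (common loci with map positions),
    and the stage-count report.
    """
    cfg.validate()
    pops = panel.populations
    if len(pops) != 2:
        raise ValueError(f"expected exactly 2 populations, found {len(pops)}")

    masks: dict[str, np.ndarray] = {}
    per_pop_counts: dict[str, dict[str, int]] = {}
    per_pop_panels: dict[str, GenotypePanel] = {}
    for label in pops:
        mask, counts = _population_survivors(panel, label, cfg)
        masks[label] = mask
        per_pop_counts[label] = counts
        per_pop_panels[label] = panel.subset(
            loci=mask, individuals=panel.population_labels == label
        )

    common_mask = masks[pops[0]] & masks[pops[1]]
    common = panel.subset(loci=common_mask)
    if lmap is not None:
        mapped_ids = [lid for lid in common.locus_ids if lid in lmap]
    else:
        mapped_ids = []
    mapped = common.subset(loci=mapped_ids)

    report = FilterReport(
        per_population=per_pop_counts,
        common=common.n_loci,
        mapped=mapped.n_loci,
    )
    report.validate()
    return QCResult(
        per_population=per_pop_panels, common=common, mapped=mapped, report=report
    )
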