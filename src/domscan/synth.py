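"""Synthetic wild/hatchery SNP-panel pairs with known truth labels.

The generator emulates the structure of an early-phase domestication study:
two samples drawn from populations that split t generations ago and have
since drifted independently (multilocus FST of order t/(2Ne), i.e. 0.005-0.03
for the study's Ne of a few hundred and 5-9 generations), a few thousand
biallelic SNPs spread over ~29 linkage groups, a few dozen diploids per
sample, sporadically missing genotypes, genotyping artifacts (all-missing,
monomorphic and tri-allelic loci), and optionally a minority of loci with
elevated wild/hatchery differentiation standing in for selected loci.

Neutral drift is simulated on allele frequencies (a binomial Wright-Fisher
step per generation); "selected" loci instead draw the domesticated-strain
frequency from a Balding-Nichols Beta distribution around the ancestral
frequency with F equal to the requested target FST. Individual-based
machinery (linkage, actual selection) lives in :mod:`domscan.driftsim`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING_ALLELE, GenotypePanel, LinkageMap
from .io import panel_from_dosage

_NUCLEOTIDES = np.array(["A", "C", "G", "T"])


@dataclass
class SynthSpec:
    """Parameters of one synthetic wild/hatchery pair.

    Defaults mirror the largest of the study's pairs: 44 wild + 52 hatchery
    individuals, ~5,000 loci on 29 linkage groups of 85 cM, effective sizes
    of 330 and a split roughly 8 generations back (expected multilocus FST
    ~= 8/660 ~= 0.012). Artifacts and selected loci are off by default.
    """

    n_loci: int = 5000
    n_linkage_groups: int = 29
    lg_length: float = 85.0
    n_wild: int = 44
    n_dom: int = 52
    ne_wild: int = 330
    ne_dom: int = 330
    t: int = 8
    ancestral_freq_low: float = 0.05
    ancestral_freq_high: float = 0.95
    missing_rate: float = 0.02
    n_selected: int = 0
    selected_fst: float = 0.25
    artifact_counts: tuple[int, int, int] = (0, 0, 0)  # all-missing, mono, tri
    wild_label: str = "wild"
    dom_label: str = "dom"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_loci, self.n_linkage_groups, self.n_wild, self.n_dom) < 1:
            raise ValueError("counts must be positive")
        if min(self.ne_wild, self.ne_dom) < 1:
            raise ValueError("effective sizes must be >= 1")
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0.0 < self.selected_fst < 1.0:
            raise ValueError("selected_fst must be in (0, 1)")
        if self.n_selected > self.n_loci:
            raise ValueError("n_selected cannot exceed n_loci")
        if any(c < 0 for c in self.artifact_counts):
            raise ValueError("artifact counts must be non-negative")


@dataclass
class TruthLabels:
    """Per-locus ground truth: ``neutral``, ``selected`` or ``artifact:<kind>``."""

    labels: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, locus_id: str) -> str:
        return self.labels[locus_id]

    def loci_with(self, label: str) -> list[str]:
        return [lid for lid, lab in self.labels.items() if lab == label]


def _drift(freq: np.ndarray, ne: int, t: int, rng: np.random.Generator) -> np.ndarray:
    q = freq.copy()
    for _ in range(t):
        q = rng.binomial(2 * ne, q) / (2 * ne)
    return q


def generate_pair(spec: SynthSpec) -> tuple[GenotypePanel, LinkageMap, TruthLabels]:
    """Generate one wild/hatchery panel pair, its map, and truth labels.

    The seed fully determines the output (same seed, byte-identical files
    after :func:`domscan.io.write_panel`).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_body = spec.n_loci  # neutral + selected loci; artifacts appended after
    n_neutral = n_body - spec.n_selected

    q0 = rng.uniform(spec.ancestral_freq_low, spec.ancestral_freq_high, size=n_body)
    freq_wild = _drift(q0, spec.ne_wild, spec.t, rng)
    freq_dom = _drift(q0, spec.ne_dom, spec.t, rng)
    if spec.n_selected:
        sel = slice(n_neutral, n_body)
        # selected_fst is the target PAIRWISE differentiation. The pair's
        # FST is roughly the mean of the two populations' divergences from
        # the ancestor, so the hatchery-side Balding-Nichols F is set to
        # 2*target minus the wild side's expected drift.
        drift_wild = 1.0 - (1.0 - 1.0 / (2.0 * spec.ne_wild)) ** spec.t
        f = min(max(2.0 * spec.selected_fst - drift_wild, 1e-6), 0.98)
        shape = (1.0 - f) / f
        freq_dom[sel] = rng.beta(q0[sel] * shape, (1.0 - q0[sel]) * shape)

    n_total_ind = spec.n_wild + spec.n_dom
    dosage_body = np.empty((n_total_ind, n_body), dtype=np.int8)
    dosage_body[: spec.n_wild] = rng.binomial(
        2, freq_wild, size=(spec.n_wild, n_body)
    )
    dosage_body[spec.n_wild :] = rng.binomial(
        2, freq_dom, size=(spec.n_dom, n_body)
    )
    if spec.missing_rate > 0:
        mask = rng.random(dosage_body.shape) < spec.missing_rate
        dosage_body[mask] = -1

    # Per-locus ref/alt characters (two distinct nucleotides).
    pair_idx = rng.integers(0, 4, size=n_body)
    offset = rng.integers(1, 4, size=n_body)
    ref_sym = _NUCLEOTIDES[pair_idx]
    alt_sym = _NUCLEOTIDES[(pair_idx + offset) % 4]

    labels: dict[str, str] = {}
    body_ids = np.array([f"S{j:05d}" for j in range(n_body)], dtype=object)
    for j, lid in enumerate(body_ids):
        labels[lid] = "selected" if j >= n_neutral else "neutral"

    pops = np.array(
        [spec.wild_label] * spec.n_wild + [spec.dom_label] * spec.n_dom, dtype=object
    )
    panel = panel_from_dosage(
        dosage_body,
        population_labels=pops,
        locus_ids=body_ids,
        ref_alleles=ref_sym,
        alt_alleles=alt_sym,
    )
    alleles = panel.alleles

    # Artifact loci appended last: all-missing, monomorphic, tri-allelic.
    n_miss, n_mono, n_tri = spec.artifact_counts
    art_cols = []
    art_ids = []
    k = 0
    for _ in range(n_miss):
        art_cols.append(np.full((n_total_ind, 2), MISSING_ALLELE, dtype="<U1"))
        art_ids.append(f"AM{k:03d}")
        labels[art_ids[-1]] = "artifact:all_missing"
        k += 1
    for _ in range(n_mono):
        sym = rng.choice(_NUCLEOTIDES)
        art_cols.append(np.full((n_total_ind, 2), sym, dtype="<U1"))
        art_ids.append(f"AM{k:03d}")
        labels[art_ids[-1]] = "artifact:monomorphic"
        k += 1
    for _ in range(n_tri):
        syms = rng.choice(_NUCLEOTIDES, size=3, replace=False)
        draws = rng.choice(syms, size=(n_total_ind, 2), p=[0.5, 0.3, 0.2])
        # force all three symbols present
        draws[0] = [syms[0], syms[1]]
        draws[1] = [syms[2], syms[2]]
        art_cols.append(draws.astype("<U1"))
        art_ids.append(f"AM{k:03d}")
        labels[art_ids[-1]] = "artifact:triallelic"
        k += 1
    if art_cols:
        alleles = np.concatenate(
            [alleles] + [c[:, None, :] for c in art_cols], axis=1
        )
    locus_ids = np.concatenate([body_ids, np.asarray(art_ids, dtype=object)])

    panel = GenotypePanel(
        individual_ids=panel.individual_ids,
        population_labels=pops,
        locus_ids=locus_ids,
        alleles=alleles,
    )

    n_all = len(locus_ids)
    lgs = rng.integers(0, spec.n_linkage_groups, size=n_all)
    positions = rng.uniform(0.0, spec.lg_length, size=n_all)
    lmap = LinkageMap(
        locus_ids,
        [f"LG{g + 1:02d}" for g in lgs],
        positions,
    )
    return panel, lmap, TruthLabels(labels)


def fixture_panel() -> tuple[GenotypePanel, LinkageMap, TruthLabels]:
    """Deterministic 2x12-individual, 40-locus panel used across the tests.

    Planted loci (identical in both populations):

    * ``F34`` all genotypes missing           -> fails the missingness filter
    * ``F35`` monomorphic                     -> fails the allele-count filter
    * ``F36`` tri-allelic                     -> fails the allele-count filter
    * ``F37``/``F38`` one heterozygote each   -> MAF 1/24 < 5%
    * ``F39`` 6 AA / 6 CC, zero heterozygotes -> exact-HWE p = 3.4e-4 < 0.001

    The remaining 34 loci pass every default filter, so the QC retention
    counts are 40 -> 39 -> 37 -> 35 -> 34 in each population and the common
    set holds 34 loci.
    """
    n_per_pop = 12
    n_ind = 2 * n_per_pop
    # Genotype count patterns (n_AA, n_Aa, n_aa) that pass MAF and HWE.
    good_patterns = [(3, 6, 3), (2, 6, 4), (4, 6, 2), (4, 5, 3), (2, 7, 3)]

    def expand(pattern: tuple[int, int, int]) -> list[int]:
        n0, n1, n2 = pattern
        return [0] * n0 + [1] * n1 + [2] * n2

    cols: list[list[int]] = []
    for j in range(34):
        cols.append(expand(good_patterns[j % len(good_patterns)]))
    dosage = np.array(cols, dtype=np.int8).T  # (12, 34) one population block
    dosage = np.vstack([dosage, dosage[::-1]])  # second population, reshuffled rows
    # a little scattered missingness on one safe locus (2/24 = 8.3% < 30%)
    dosage[0, 5] = -1
    dosage[n_per_pop, 5] = -1

    pops = np.array(["wild"] * n_per_pop + ["dom"] * n_per_pop, dtype=object)
    ids = np.array([f"fix{i:02d}" for i in range(n_ind)], dtype=object)
    base_ids = np.array([f"F{j:02d}" for j in range(34)], dtype=object)
    panel_body = panel_from_dosage(
        dosage, pops, individual_ids=ids, locus_ids=base_ids
    )
    alleles = panel_body.alleles

    def col_from_pairs(pairs: list[tuple[str, str]]) -> np.ndarray:
        one_pop = np.asarray(pairs, dtype="<U1")
        return np.vstack([one_pop, one_pop])[:, None, :]

    extra_cols = []
    labels = {lid: "neutral" for lid in base_ids}
    # F34: all-missing
    extra_cols.append(col_from_pairs([(MISSING_ALLELE, MISSING_ALLELE)] * n_per_pop))
    # F35: monomorphic
    extra_cols.append(col_from_pairs([("G", "G")] * n_per_pop))
    # F36: tri-allelic
    tri = [("A", "C")] * 4 + [("A", "G")] * 4 + [("A", "A")] * 4
    extra_cols.append(col_from_pairs(tri))
    # F37, F38: single heterozygote -> MAF 1/24
    low_maf = [("A", "T")] + [("A", "A")] * (n_per_pop - 1)
    extra_cols.append(col_from_pairs(low_maf))
    extra_cols.append(col_from_pairs(low_maf))
    # F39: strong heterozygote deficit (6 AA / 6 CC)
    hwe = [("A", "A")] * 6 + [("C", "C")] * 6
    extra_cols.append(col_from_pairs(hwe))

    extra_ids = [f"F{j:02d}" for j in range(34, 40)]
    for lid, lab in zip(
        extra_ids,
        [
            "artifact:all_missing",
            "artifact:monomorphic",
            "artifact:triallelic",
            "artifact:low_maf",
            "artifact:low_maf",
            "artifact:hwe",
        ],
    ):
        labels[lid] = lab

    alleles = np.concatenate([alleles] + extra_cols, axis=1)
    locus_ids = np.concatenate([base_ids, np.asarray(extra_ids, dtype=object)])
    panel = GenotypePanel(
        individual_ids=ids,
        population_labels=pops,
        locus_ids=locus_ids,
        alleles=alleles,
    )
    lgs = [f"LG{1 + j % 4:02d}" for j in range(40)]
    positions = [2.5 * (j // 4) for j in range(40)]
    lmap = LinkageMap(locus_ids, lgs, positions)
    return panel, lmap, TruthLabels(labels)
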