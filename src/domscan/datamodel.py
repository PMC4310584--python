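"""Core data containers for paired wild/hatchery SNP analyses.

A :class:`GenotypePanel` holds unphased biallelic genotype calls for the
individuals of a wild population and its domesticated (hatchery) strain.
Genotypes are kept in two synchronised representations:

* the raw allele characters as read from disk (``alleles``), which preserve
  artifact loci (all-missing, monomorphic, tri-allelic) exactly and make
  file round-trips byte-faithful, and
* an alternate-allele dosage matrix (``genotypes``) with values in
  ``{0, 1, 2, MISSING}``, defined only at "recodable" loci (exactly two
  allele symbols observed in the pooled sample).

The alternate allele at a recodable locus is the minor allele of the pooled
pair; ties are broken lexicographically (the later symbol becomes the
alternate). This polarity is arbitrary but deterministic, and none of the
downstream statistics depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for an absent genotype call in the dosage matrix.
MISSING: int = -1

#: Character used for a missing allele in the text dialect (PED convention).
MISSING_ALLELE: str = "0"


class PanelError(ValueError):
    """Raised for structurally invalid panels or panel files."""


def _as_str_array(values: Sequence[str]) -> np.ndarray:
    return np.asarray(list(values), dtype=object)


@dataclass
class GenotypePanel:
    """Individuals x loci biallelic genotype matrix with population labels.

    Parameters
    ----------
    individual_ids
        One id per individual (rows).
    population_labels
        One population label per individual.
    locus_ids
        One unique id per locus (columns).
    alleles
        ``(n_individuals, n_loci, 2)`` array of single-character allele
        symbols; ``"0"`` marks a missing allele.
    """

    individual_ids: np.ndarray
    population_labels: np.ndarray
    locus_ids: np.ndarray
    alleles: np.ndarray

    genotypes: np.ndarray = field(init=False, repr=False)
    allele_registry: list[tuple[str, ...]] = field(init=False, repr=False)
    ref_alleles: np.ndarray = field(init=False, repr=False)
    alt_alleles: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.individual_ids = _as_str_array(self.individual_ids)
        self.population_labels = _as_str_array(self.population_labels)
        self.locus_ids = _as_str_array(self.locus_ids)
        self.alleles = np.asarray(self.alleles, dtype="<U1")
        n_ind, n_loc = len(self.individual_ids), len(self.locus_ids)
        if self.population_labels.shape != (n_ind,):
            raise PanelError("one population label required per individual")
        if self.alleles.shape != (n_ind, n_loc, 2):
            raise PanelError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"({n_ind}, {n_loc}, 2)"
            )
        if len(set(self.locus_ids)) != n_loc:
            raise PanelError("duplicate locus ids")
        self._recode()

    # ------------------------------------------------------------------
    def _recode(self) -> None:
        n_ind, n_loc = self.alleles.shape[:2]
        registry: list[tuple[str, ...]] = []
        ref = np.empty(n_loc, dtype="<U1")
        alt = np.empty(n_loc, dtype="<U1")
        geno = np.full((n_ind, n_loc), MISSING, dtype=np.int8)
        for j in range(n_loc):
            col = self.alleles[:, j, :]
            symbols = col[col != MISSING_ALLELE]
            uniq, counts = np.unique(symbols, return_counts=True)
            registry.append(tuple(uniq))
            if len(uniq) != 2:
                ref[j] = alt[j] = ""
                continue
            # alternate allele = pooled minor; tie -> lexicographically later
            if counts[0] == counts[1]:
                r, a = uniq[0], uniq[1]
            elif counts[0] > counts[1]:
                r, a = uniq[0], uniq[1]
            else:
                r, a = uniq[1], uniq[0]
            ref[j], alt[j] = r, a
            called = (col[:, 0] != MISSING_ALLELE) & (col[:, 1] != MISSING_ALLELE)
            dose = (col[:, 0] == a).astype(np.int8) + (col[:, 1] == a).astype(np.int8)
            geno[called, j] = dose[called]
        self.allele_registry = registry
        self.ref_alleles = ref
        self.alt_alleles = alt
        self.genotypes = geno

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.population_labels:
            seen.setdefault(lab, None)
        return list(seen)

    def recodable(self) -> np.ndarray:
        """Boolean mask of loci with exactly two observed allele symbols."""
        return np.array([len(r) == 2 for r in self.allele_registry])

    # ------------------------------------------------------------------
    def subset(
        self,
        loci: Sequence[str] | np.ndarray | None = None,
        individuals: np.ndarray | None = None,
    ) -> "GenotypePanel":
        """Return a new panel restricted to given loci and/or individuals.

        ``loci`` may be locus ids (original order is preserved) or a boolean
        mask; ``individuals`` is a boolean mask over rows.
        """
        if loci is None:
            col_idx = np.arange(self.n_loci)
        else:
            loci = np.asarray(loci)
            if loci.dtype == bool:
                col_idx = np.flatnonzero(loci)
            else:
                keep = set(loci.tolist())
                col_idx = np.array(
                    [j for j, lid in enumerate(self.locus_ids) if lid in keep],
                    dtype=int,
                )
        if individuals is None:
            row_idx = np.arange(self.n_individuals)
        else:
            row_idx = np.flatnonzero(np.asarray(individuals, dtype=bool))
        return GenotypePanel(
            individual_ids=self.individual_ids[row_idx],
            population_labels=self.population_labels[row_idx],
            locus_ids=self.locus_ids[col_idx],
            alleles=self.alleles[np.ix_(row_idx, col_idx)],
        )

    def population_panel(self, label: str) -> "GenotypePanel":
        mask = self.population_labels == label
        if not mask.any():
            raise PanelError(f"unknown population label {label!r}")
        return self.subset(individuals=mask)

    def split_populations(self) -> dict[str, "GenotypePanel"]:
        return {lab: self.population_panel(lab) for lab in self.populations}

    # ------------------------------------------------------------------
    def dosage_counts(self, label: str | None = None):
        """Per-locus genotype counts (n0, n1, n2) over non-missing calls.

        Restricted to one population when ``label`` is given. Returns a
        4-tuple of arrays ``(n_hom_ref, n_het, n_hom_alt, n_called)``.
        """
        if label is None:
            g = self.genotypes
        else:
            g = self.genotypes[self.population_labels == label]
        n0 = (g == 0).sum(axis=0)
        n1 = (g == 1).sum(axis=0)
        n2 = (g == 2).sum(axis=0)
        return n0, n1, n2, n0 + n1 + n2

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            np.array_equal(self.individual_ids, other.individual_ids)
            and np.array_equal(self.population_labels, other.population_labels)
            and np.array_equal(self.locus_ids, other.locus_ids)
            and np.array_equal(self.alleles, other.alleles)
        )


class LinkageMap:
    """Mapping of locus id -> (linkage group, position in cM).

    Only a subset of a panel's loci need be mapped; scans and LD analyses
    silently restrict themselves to mapped loci, mirroring the distinction
    between "common" and "mapped" SNP sets.
    """

    def __init__(
        self,
        locus_ids: Sequence[str],
        linkage_groups: Sequence[str],
        positions_cm: Sequence[float],
    ) -> None:
        locus_ids = list(locus_ids)
        if len(set(locus_ids)) != len(locus_ids):
            raise PanelError("duplicate locus id in map")
        pos = np.asarray(positions_cm, dtype=float)
        if not np.all(np.isfinite(pos)):
            raise PanelError("map positions must be finite")
        if np.any(pos < 0):
            raise PanelError("map positions must be non-negative cM")
        self.frame = pd.DataFrame(
            {
                "linkage_group": [str(g) for g in linkage_groups],
                "position_cm": pos,
            },
            index=pd.Index(locus_ids, name="locus_id"),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LinkageMap":
        return cls(frame.index, frame["linkage_group"], frame["position_cm"])

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.frame.index

    def __getitem__(self, locus_id: str) -> tuple[str, float]:
        row = self.frame.loc[locus_id]
        return str(row["linkage_group"]), float(row["position_cm"])

    @property
    def locus_ids(self) -> list[str]:
        return list(self.frame.index)

    def linkage_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.frame["linkage_group"]:
            seen.setdefault(g, None)
        return list(seen)

    def subset(self, locus_ids: Iterable[str]) -> "LinkageMap":
        keep = [lid for lid in self.frame.index if lid in set(locus_ids)]
        return LinkageMap.from_frame(self.frame.loc[keep])

    def equals(self, other: "LinkageMap") -> bool:
        return self.frame.equals(other.frame)


@dataclass
class PairConfig:
    """Analysis thresholds for one wild/domesticated pair.

    ``generations_since_split`` (t) feeds the moment estimator
    Ne = t / (2 FST). All thresholds default to the study's printed values:
    30% missingness, 5% MAF, exact-HWE alpha 0.001, |z| = 2.58 for the
    standardized-heterozygosity outlier call, 10,000 permutations and a
    0.001 region alpha for the smoothed scans, and 1,000 bootstrap
    replicates for confidence intervals.
    """

    wild_label: str = "wild"
    domesticated_label: str = "dom"
    generations_since_split: float = 8.5
    missing_max: float = 0.30
    maf_min: float = 0.05
    hwe_alpha: float = 0.001
    lnrh_z: float = 2.58
    perm_reps: int = 10_000
    region_alpha: float = 0.001
    bootstrap_reps: int = 1_000
    seed: int = 0

    def validate(self) -> None:
        if self.generations_since_split <= 0:
            raise ValueError("generations_since_split must be > 0")
        for name in ("missing_max", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("hwe_alpha", "region_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.lnrh_z <= 0:
            raise ValueError("lnrh_z must be positive")
        if self.perm_reps < 1:
            raise ValueError("perm_reps must be >= 1")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.wild_label == self.domesticated_label:
            raise ValueError("wild and domesticated labels must differ")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PairConfig":
        cfg = cls(**dict(mapping))
        cfg.validate()
        return cfg
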