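"""Readers and writers for the plain-text genotype/map dialect.

Genotype file: UTF-8, newline-terminated, whitespace-delimited. The first
line is a header ``#pop ind L1 L2 ...`` naming the loci; every following row
is ``population_label individual_id`` plus two allele characters per locus
(``A/C/G/T``, ``0`` for a missing allele).

Map file: three whitespace-delimited columns ``linkage_group locus_id
position_cM`` (PLINK ``.map`` layout with cM in place of bp), no header.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .datamodel import MISSING_ALLELE, GenotypePanel, LinkageMap, PanelError

_HEADER_PREFIX = "#pop ind"


def read_panel(
    genotype_path: str | os.PathLike,
    map_path: str | os.PathLike | None = None,
) -> tuple[GenotypePanel, LinkageMap | None]:
    """Read a genotype panel and (optionally) its linkage map.

    The map may cover only a subset of the panel's loci; unmapped loci are
    legal and are simply excluded from map-based analyses.
    """
    genotype_path = Path(genotype_path)
    lines = genotype_path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#"):
        raise PanelError(f"{genotype_path}: line 1: missing '#pop ind ...' header")
    header = lines[0].lstrip("#").split()
    if header[:2] != ["pop", "ind"]:
        raise PanelError(f"{genotype_path}: line 1: malformed header")
    locus_ids = header[2:]
    if len(set(locus_ids)) != len(locus_ids):
        raise PanelError(f"{genotype_path}: line 1: duplicate locus id")
    n_loci = len(locus_ids)
    expected = 2 + 2 * n_loci

    pops: list[str] = []
    inds: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != expected:
            raise PanelError(
                f"{genotype_path}: line {lineno}: expected {expected} fields "
                f"for individual with {n_loci} loci, got {len(fields)}"
            )
        for tok in fields[2:]:
            if len(tok) != 1:
                raise PanelError(
                    f"{genotype_path}: line {lineno}: allele {tok!r} is not a "
                    "single character"
                )
        pops.append(fields[0])
        inds.append(fields[1])
        rows.append(fields[2:])

    alleles = np.asarray(rows, dtype="<U1").reshape(len(rows), n_loci, 2)
    panel = GenotypePanel(
        individual_ids=np.asarray(inds, dtype=object),
        population_labels=np.asarray(pops, dtype=object),
        locus_ids=np.asarray(locus_ids, dtype=object),
        alleles=alleles,
    )
    lmap = read_map(map_path) if map_path is not None else None
    return panel, lmap


def read_map(map_path: str | os.PathLike) -> LinkageMap:
    map_path = Path(map_path)
    groups: list[str] = []
    loci: list[str] = []
    positions: list[float] = []
    for lineno, line in enumerate(
        map_path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 3:
            raise PanelError(
                f"{map_path}: line {lineno}: expected 3 fields, got {len(fields)}"
            )
        try:
            pos = float(fields[2])
        except ValueError as exc:
            raise PanelError(
                f"{map_path}: line {lineno}: bad position {fields[2]!r}"
            ) from exc
        groups.append(fields[0])
        loci.append(fields[1])
        positions.append(pos)
    if len(set(loci)) != len(loci):
        raise PanelError(f"{map_path}: duplicate locus id")
    return LinkageMap(loci, groups, positions)


def write_panel(
    panel: GenotypePanel,
    lmap: LinkageMap | None,
    out_prefix: str | os.PathLike,
) -> tuple[Path, Path]:
    """Write ``<prefix>.geno`` and ``<prefix>.map``; round-trips bit-exactly.

    A missing genotype is emitted as ``0 0``. An empty map (or ``None``)
    yields an empty map file.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    geno_path = out_prefix.with_suffix(".geno")
    map_path = out_prefix.with_suffix(".map")

    with open(geno_path, "w", encoding="utf-8", newline="\n") as fh:
        header = _HEADER_PREFIX
        if panel.n_loci:
            header += " " + " ".join(panel.locus_ids)
        fh.write(header + "\n")
        for i in range(panel.n_individuals):
            fields = [panel.population_labels[i], panel.individual_ids[i]]
            fields.extend(panel.alleles[i].ravel())
            fh.write(" ".join(fields) + "\n")

    with open(map_path, "w", encoding="utf-8", newline="\n") as fh:
        if lmap is not None:
            for lid, row in lmap.frame.iterrows():
                fh.write(
                    f"{row['linkage_group']} {lid} "
                    f"{format(row['position_cm'], '.17g')}\n"
                )
    return geno_path, map_path


def panel_from_dosage(
    dosage: np.ndarray,
    population_labels: np.ndarray,
    individual_ids: np.ndarray | None = None,
    locus_ids: np.ndarray | None = None,
    ref_alleles: np.ndarray | None = None,
    alt_alleles: np.ndarray | None = None,
    missing_code: int = -1,
) -> GenotypePanel:
    """Build a panel from an alternate-allele dosage matrix.

    Heterozygotes are emitted with alleles in (ref, alt) order, so allele
    order carries no phase information. Convenience for the generators.
    """
    dosage = np.asarray(dosage)
    n_ind, n_loc = dosage.shape
    if individual_ids is None:
        individual_ids = np.array([f"ind{i:04d}" for i in range(n_ind)], dtype=object)
    if locus_ids is None:
        locus_ids = np.array([f"L{j:05d}" for j in range(n_loc)], dtype=object)
    if ref_alleles is None:
        ref_alleles = np.full(n_loc, "A", dtype="<U1")
    if alt_alleles is None:
        alt_alleles = np.full(n_loc, "C", dtype="<U1")
    alleles = np.empty((n_ind, n_loc, 2), dtype="<U1")
    ref = np.broadcast_to(ref_alleles, (n_ind, n_loc))
    alt = np.broadcast_to(alt_alleles, (n_ind, n_loc))
    alleles[..., 0] = np.where(dosage >= 1, alt, ref)
    alleles[..., 1] = np.where(dosage == 2, alt, ref)
    miss = dosage == missing_code
    alleles[miss, :] = MISSING_ALLELE
    return GenotypePanel(
        individual_ids=individual_ids,
        population_labels=np.asarray(population_labels, dtype=object),
        locus_ids=locus_ids,
        alleles=alleles,
    )
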