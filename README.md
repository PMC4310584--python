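# domscan

Genome scans for the early phases of domestication and captive breeding in
paired wild/hatchery SNP panels.

## The problem

Hatchery strains of Atlantic salmon (and other farmed fish) have typically
been separated from their wild source populations for only 5–10 generations.
Selection in the hatchery environment — intentional (growth, maturation) or
inadvertent — should leave local footprints in the genome: loci whose
wild/hatchery allele-frequency differentiation exceeds the genome-wide drift
background, or whose diversity has dropped in one population. At such short
time scales those footprints are faint, so the analysis needs careful
per-locus statistics, genome-wide null distributions, and forward simulations
to say when a footprint is even detectable.

`domscan` implements that complete workflow for two-population biallelic SNP
panels:

* **QC** — the ordered per-population filter pipeline (missingness > 30%,
  allele-count ∉ {2}, MAF < 5%, exact Hardy–Weinberg test at α = 0.001),
  then the common and mapped intersections, with a retention report per stage.
* **popstats** — Nei's unbiased heterozygosities; Weir–Cockerham (1984)
  F<sub>IS</sub> and F<sub>ST</sub> (θ̂) with 1,000-replicate bootstrap CIs
  over loci; Weir–Hill population-specific F<sub>ST</sub> (β, matching
  proportions); standardized heterozygosity LnRH,
  θ_H = ½[(1/(1−H_e))² − 1], lnRH = ln(θ_H^wild / θ_H^dom), z-standardized
  with ±2.58 outlier thresholds (two-sided P = 0.01); and the moment
  formulas N_e = t/(2 F_ST) and F = (H_wild − H_dom)/H_wild.
* **scan** — local-linear Gaussian-kernel smoothing of per-locus θ̂ or LnRH
  along each linkage group (plug-in bandwidth, 401-point grid), with
  genome-wide permutation p-values (10,000 replicates by default) and region
  calling at P < 0.001.
* **ld** — two-locus EM haplotype frequencies for unphased genotypes, r² and
  D′, per-linkage-group heat-map matrices, Hill–Weir
  E[r²] = (10+C)/((2+C)(11+C)) · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]
  decay fitting (C = ρd), and the half-decay distance.
* **synth** — a calibrated generator of wild/hatchery panel pairs (binomial
  Wright–Fisher drift, Balding–Nichols "selected" loci, genotyping
  artifacts, missingness) with truth labels, for power studies and testing.
* **driftsim** — a forward-time individual-based simulator of one
  quantitative trait under divergent Gaussian stabilizing selection (5 or 20
  linked QTLs plus 177 linked neutral markers on one chromosome, N = 200 per
  population, Haldane recombination, no mutation/migration), sweeping a
  12-scenario grid of optima {0.1, 0.5, 5} × QTL counts {5, 20} × effect
  variances {0.1, 1} with matched no-selection controls.

## Worked example

```python
from domscan.synth import SynthSpec, generate_pair
from domscan.qc import apply_filters
from domscan.datamodel import PairConfig
from domscan import popstats

spec = SynthSpec(n_loci=4000, n_wild=44, n_dom=52, ne_wild=330, ne_dom=330,
                 t=8, missing_rate=0.02, artifact_counts=(2, 2, 2), seed=42)
panel, lmap, truth = generate_pair(spec)
cfg = PairConfig(generations_since_split=8.5, seed=42)
res = apply_filters(panel, lmap, cfg)
print(res.report.to_frame())

summary = popstats.pair_summary(res.common, "wild", "dom",
                                t=cfg.generations_since_split, seed=42)
print(f"FST = {summary.fst:.4f} (95% CI {summary.fst_ci[0]:.4f}-{summary.fst_ci[1]:.4f})")
print(f"Ne (moment) = {summary.ne_moment:.0f}")
print(f"diversity loss F = {summary.diversity_loss_f:.4f}")
```

prints

```
            input  missingness  allele_count   maf   hwe  common  mapped
population
wild         4006         4004          3990  3821  3821    3709    3709
dom          4006         4004          3991  3821  3819    3709    3709
FST = 0.0114 (95% CI 0.0104-0.0125)
Ne (moment) = 372
diversity loss F = 0.0014
```

Reading this: of 4,006 generated loci (4,000 + 6 planted artifacts), each
population loses the artifact and low-information loci stage by stage; 3,709
loci survive in both. Eight generations of drift at N_e = 330 leaves a
multilocus F<sub>ST</sub> of ~0.011 — the weak background differentiation
typical of early domestication — and inverting the drift expectation returns
N_e ≈ 372. The diversity loss between the two samples is negligible, as
expected without selection.

The same pipeline runs from the shell:

```bash
domscan simulate-data --spec spec.yaml --out data/pair
domscan filter --geno data/pair.geno --map data/pair.map --out qc/pair
domscan stats  --geno qc/pair_common.geno --out stats/pair
domscan scan   --stats stats/pair_locus_stats.tsv --map data/pair.map \
               --stat fst --nperm 10000 --alpha 0.001 --seed 7 --out scan/pair
domscan ld     --geno qc/pair_common.geno --map qc/pair_common.map \
               --pop wild --max-dist 50 --out ld/pair
domscan simulate-qtl --scenario Sim_I --replicates 100 --seed 7 --out traj.tsv
domscan run    --config run.yaml        # everything, with a JSON manifest
```

## Layout

```
src/domscan/
  datamodel.py   GenotypePanel / LinkageMap / PairConfig containers
  io.py          PED-like genotype + map text dialect (round-trip exact)
  synth.py       synthetic panel pairs with truth labels
  qc.py          exact HWE test and the ordered filter pipeline
  popstats.py    heterozygosities, FIS/FST/beta, LnRH, moment formulas
  scan.py        kernel smoothing, permutation p-values, region calling
  ld.py          EM haplotype frequencies, r2/D', Hill-Weir decay
  driftsim.py    forward-time QTL/neutral divergence simulator
  pipeline.py    one-config orchestration with a run manifest
  cli.py         `domscan` command group
docs/methods.md  modelling assumptions, parameter choices, limitations
```
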