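# Methods

This note records the statistical models implemented in `domscan`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
written down. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Genotypes are unphased biallelic calls for two samples — a wild population
and its domesticated (hatchery) strain. Internally each locus is stored both
as raw allele characters (so artifact loci and file round-trips are exact)
and as an alternate-allele dosage in {0, 1, 2, missing}. The alternate
allele is the pooled minor allele, ties broken lexicographically; every
statistic in the package is invariant to that polarity choice. A locus is
"recodable" only when exactly two allele symbols are observed; 0-, 1- and
3-symbol loci are artifacts that the QC allele-count stage must catch, so
the recoder deliberately leaves them undefined rather than guessing.

Map positions are sex-averaged centimorgans with origin 0 at each linkage
group start. A map may cover only part of a panel: unmapped loci take part
in all per-locus statistics but are excluded from the smoothed scans and LD.

## QC pipeline

Filters run per population, in this order: (1) missingness strictly greater
than 30% of individuals; (2) observed allele-symbol count ≠ 2; (3) minor
allele frequency (over non-missing calls) strictly below 5%; (4) exact
Hardy–Weinberg test p < 0.001. The "common" panel is the intersection of the
two populations' survivors, and "mapped" additionally requires a map entry.
Running allele-count removal before or after the missingness stage yields
the same final sets but different intermediate counts; the order above is
the one whose stage counts the retention report mirrors.

The HWE test enumerates every heterozygote count compatible with the
observed allele counts and sums the probabilities of all configurations no
more probable than the observed one. This probability-mass two-sidedness
flags both heterozygote deficit and excess, which matters here because
hatchery panels show mild excess. Note the smallest attainable p grows as
samples shrink: with 12 individuals a fully heterozygous locus has
p ≈ 0.0019 and therefore survives an α = 0.001 filter; a het-free 6/0/6
locus (p ≈ 3.4 × 10⁻⁴) does not. A numerical tolerance of 1e−12 treats
float-equal probabilities as ties, matching exact rational enumeration.

Thresholds are strict inequalities with a 1e−9 relative guard on the
missingness fraction so that an exactly-at-threshold locus (e.g. 9 of 30
missing) is retained, as "greater than 30%" demands.

## Estimators

* **Heterozygosity**: Nei's unbiased estimator
  H_e = (2n/(2n−1))(1 − p² − q²) per locus and population, H_o the observed
  heterozygote fraction, both over non-missing calls. The unbiased form is
  also what makes the matching proportions below unbiased.
* **F_IS / F_ST**: Weir & Cockerham (1984) variance components for r = 2
  samples of unequal size. Multilocus values are ratios of sums (Σa/Σ(a+b+c)
  and Σb/Σ(b+c)), the form with the least ratio bias; loci with zero total
  components (pooled-monomorphic) drop out of the sums. Confidence intervals
  are 2.5/97.5 percentile bootstrap over loci, 1,000 replicates, seeded.
  Percentile (not BCa) because the target is a descriptive interval over
  loci, and it is what the field reports.
* **Population-specific F_ST** (Weir & Hill 2002) in matching-proportion
  form: within-population matching M_i = 1 − H_e (unbiased), between-pair
  matching M_B = p₁p₂ + (1−p₁)(1−p₂), and β_i = Σ(M_i − M_B)/Σ(1 − M_B) over
  loci. β_i can be negative (population closer to the pair average than
  expected); the two βs, weighted by the common denominator, average to the
  overall matching-based differentiation — a test asserts this identity.
* **LnRH**: θ_H = ½[(1/(1−H_e))² − 1] per population, lnRH the log ratio
  wild/domesticated, z-standardized over defined loci. θ_H is a
  stepwise-mutation variability estimator; applying it to SNP H_e is the
  standard usage for this statistic and is kept as-is, with the caveat that
  only the empirical standardized distribution (not θ_H's absolute scale) is
  interpreted. Loci with H_e = 0 in one population — precisely the sweep
  candidates — stay in the scan via the floor H_e → 1/(2n). Under broad
  conditions the standardized values are approximately normal, so ±2.58
  (two-sided P = 0.01) flags outliers; expected chance outliers are
  round(0.01 · n_loci).
* **Moment formulas**: N_e = t/(2F_ST); diversity loss
  F = (H_wild − H_dom)/H_wild; markers needed to tile a map of length L at
  half-decay spacing d is ⌊L/d⌋ (with a 1e−9 guard because quotients like
  2500/0.2 sit one ulp below the integer in binary floating point).

## Kernel-smoothed permutation scan

Per-locus statistics (per-locus θ̂ for F_ST scans, z-standardized LnRH for
diversity scans) are smoothed within each linkage group by local-linear
regression with a Gaussian kernel on a 401-point equally spaced grid. Local
linear (not Nadaraya–Watson) avoids boundary bias at linkage-group ends,
where several of the interesting regions sit. The smoother is linear in the
values, so the per-group smoother matrix is computed once and reused across
permutations.

Bandwidth is chosen per linkage group by a direct plug-in rule: a global
quartic pilot fit supplies the curvature functional θ₂₂ = mean(m″(x)²) and
the residual variance σ², and h = [R(K)σ²(b−a)/(nθ₂₂)]^(1/5) with
R(K) = 1/(2√π). When the rule degenerates (fewer than 7 loci, zero span,
zero curvature) the fallback is twice the median intermarker distance.
Groups with fewer than 5 usable loci are skipped with a warning — the
generalization of manually removing isolated markers that crash smoothers at
sparse chromosome starts.

The null distribution permutes the per-locus values across all mapped
positions genome-wide (the question is deviation from the genome-wide
average, so the exchangeable unit is the value; marker spacing per group is
preserved). Bandwidths are held at their observed values across
permutations: the test targets the location of signal, not bandwidth noise.
p(grid point) = (1 + #{permuted ≥ observed})/(1 + n_perm) for the upper
tail; two-tailed doubles the smaller tail and caps at 1. The add-one rule
keeps p > 0, and numerical ties count as exceedances (conservative).
Regions are maximal runs of grid points with p below α (default 0.001),
annotated with direction (high/low at the most significant point), the
extremal smoothed value, and the nearest marker.

## Linkage disequilibrium

Two-locus haplotype frequencies come from EM over unphased diplotypes:
double heterozygotes are split between coupling and repulsion phases in
proportion to the current frequency products, iterated to |Δ| < 1e−8 or 200
iterations, initialized at linkage equilibrium. With no double
heterozygotes the result equals direct gamete counting (tested). From the
frequencies: D = p_AB − p_A p_B, D′ = |D|/D_max with the usual frequency
bounds, r² = D²/(p_A(1−p_A)p_B(1−p_B)). Pairs are restricted to one linkage
group and a maximum distance; loci monomorphic in the population are
skipped.

Decay fitting uses the Hill–Weir drift–recombination expectation with
C = ρd and n sampled chromosomes (2× individuals; the expectation needs a
chromosome count and diploid samples contribute two). ρ is fitted by
bounded nonlinear least squares. The half-decay distance solves
E[r²](d) = E[r²](0)/2 by bisection — half of the *initial* value, not of the
asymptote, because the curve never decays below its finite-sample floor
1/n. Degenerate inputs raise: a single distinct distance or a constant r²
profile carries no decay information, and fewer than 10 pairs is treated as
insufficient.

## Synthetic panel generator

Each neutral locus draws an ancestral frequency q ~ Uniform(0.05, 0.95)
(chip-like: common variants, no rare-allele tail) and evolves two
independent binomial Wright–Fisher frequency trajectories of sizes 2N_e^wild
and 2N_e^dom for t generations; diploid genotypes are then sampled under
Hardy–Weinberg and masked to missing i.i.d. Defaults emulate the largest
published pair of the study system: 44 + 52 individuals, 5,000 loci on 29
linkage groups of 85 cM, N_e = 330, t = 8, 2% missingness — giving an
expected multilocus F_ST ≈ t/(2N_e) ≈ 0.012, the weak-differentiation regime
the downstream statistics must operate in.

"Selected" loci draw the domesticated-strain frequency from a
Balding–Nichols Beta around q. The `selected_fst` parameter is the target
*pairwise* differentiation: because the pair's F_ST is roughly the mean of
the two populations' divergences from the ancestor, the Beta's F is set to
2·selected_fst minus the wild side's expected drift. Even so, realized
per-locus F_ST is highly dispersed — at skewed q the Beta mass sits on
fixation of the already-common allele, which barely differs from the wild
frequency — so individual "selected" loci are enriched in, not guaranteed
membership of, the top F_ST tail. Region-level detection of a planted
cluster is the reliable property, and is what the acceptance tests check.

Artifacts (all-missing, monomorphic, tri-allelic loci) are appended after
the body loci; the tri-allelic artifact uses a genuine third allele
character so the allele-count filter, not the recoder, must catch it.

What the generator does **not** emulate: SNP-chip ascertainment bias,
linkage between loci (each locus drifts independently; within-group LD in
generated panels is pure sampling noise), mutation, migration, and realistic
map clustering (positions are uniform per linkage group). Tests passing on
these panels therefore demonstrate estimator correctness and scan
calibration under drift, not robustness to ascertainment or background LD.

## Forward-time trait simulator

Two populations of N = 200 diploids each are founded from a common pool with
every locus at frequency 0.5 in linkage equilibrium — standing variation,
no new mutations over the ~100-generation horizon. One additive trait is
coded by 5 QTLs (positions 5, 20, 40, 50, 70 cM) or 20 QTLs (the 19
documented positions from 2 to 80 cM plus 25 cM, filling the one even gap in
that list) on a single 85-cM chromosome that also carries 177 neutral
biallelic markers, by default equally spaced. The two allelic effects per
QTL are drawn once per replicate from Normal(0, effect variance). Fitness is
Gaussian stabilizing selection w = exp(−(P − optimum)²/2ω²) with width
ω = 1 ("selection intensity 1", the standard stabilizing-selection form);
population 1's optimum is 0, population 2's is 0.1, 0.5 or 5. Environmental
variance defaults to 0 (heritability 1) and is configurable. Controls set
w ≡ 1.

Reproduction: 200 offspring per population; each draws two distinct parents
with probability proportional to fitness (monoecious, no selfing — the
simplest scheme consistent with random mating plus viability-style
selection). Fitness exponents are shifted so the fittest individual scores
exp(0); selection probabilities are invariant to this and it prevents
underflow from zeroing a whole population under the distant optimum. When
fitness is nearly one-hot the distinct-parent draw switches from rejection
to the exact leave-one-out law after 8 rounds. Gametes recombine under the
Haldane map function, crossover probability ½(1 − e^(−2d/100)) per adjacent
interval, no interference.

Multilocus Weir–Cockerham F_ST is recorded every second generation,
separately for the QTL and neutral sets, over all 400 individuals.
Replicates run on independent seed substreams, so one integer reproduces a
whole trajectory sweep. The acceptance tests run the 12-scenario grid at
100 replicates (vs the reference 1,000) and to generation 10 where only the
early-divergence contrast is asserted; controls and their matched selection
scenarios run the full 100 generations. Neutral markers share the selected
chromosome, so under strong selection their differentiation also rises above
the pure-drift expectation through hitchhiking — the relevant comparison is
always QTL vs linked-neutral, which is what the scenario contrasts assert.

## Pipeline and reproducibility

`pipeline.run_full_scan` executes generate/load → QC → statistics → F_ST
scan (upper tail) → LnRH scan (two tails) → LD (both populations) → summary,
writing every table as TSV plus a JSON manifest with the config snapshot,
per-stage seeds (spawned from one master seed), timings, record counts and
SHA-256 digests of all outputs. Re-running with the same config and seed
reproduces every digest; the test suite asserts this.

## Known limitations

* The LD module fits decay to all retained pairs without binning or
  correcting for frequency-dependent r² bias; with few pairs at short
  distances the ρ estimate is noisy.
* The plug-in bandwidth uses a single global quartic pilot per linkage
  group; heavily heteroscedastic tracks may get oversmoothed. Tests of the
  smoother therefore fix the bandwidth explicitly.
* The permutation null treats loci as exchangeable genome-wide; if true
  background LD is strong, grid-level type-I error can exceed nominal
  (the drift-panel calibration test covers the independent-locus case only).
* The exact HWE filter loses power below ~15 individuals (see above); QC on
  very small samples effectively skips stage 4.
* Beta-distributed "selected" loci model elevated differentiation, not a
  mechanistic sweep: no local LD structure, no diversity trough at linked
  sites.
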