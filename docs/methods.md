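# Methods

## Deterministic single-locus model

The core object is a two-sex viability-selection recursion on zygotic
genotype frequencies `p = (p11, p12, p22)` of an autosomal locus with a
female-beneficial allele A1 and a male-beneficial allele A2. Each
generation: (i) zygotes of both sexes start from the same genotype
frequencies; (ii) viability selection weights them by the per-sex fitness
vectors `wf = (1, 1−hf·sf, 1−sf)` and `wm = (1−sm, 1−hm·sm, 1)`;
(iii) adults mate with pair frequencies proportional to
`F = diag(wm) M diag(wf)` where `M` is the mate-choice weight matrix; and
(iv) Mendelian segregation produces the next zygote pool via the projectors
`β = diag(1, ½, 0)` and `γ = diag(0, ½, 1)`.

Parameters and defaults:

| parameter | meaning | range / default |
|---|---|---|
| `s` | male selection coefficient (`sm = s`) | `[0, 1)`, no default |
| `alpha` | female/male selection ratio (`sf = α·s`) | `> 0`, default 1 |
| `hf`, `hm` | per-sex dominance of the locally deleterious allele | `[0, 1]`, default 0.5 |
| `m1, m2, m3` | mate-choice weights (diagonal / adjacent / corner) | `≥ 0`, default 1,1,1 |

Mate-choice weights are relative: `M` and `c·M` generate identical
dynamics because the recursion normalizes by `pᵀFp` (tested as a property).
Genotype frequencies are defensively renormalized after every step and
checked to sum to one within 1e-12.

Each sex's selection coefficient enters only its own viability vector:
`wf = (1, 1−hf·sf, 1−sf)` and `wm = (1−sm, 1−hm·sm, 1)`. This is the
parameterization the post-selection frequency formulas assume, and the
implementation enforces it (a formulation in which `sm` leaked into the
female vector would break the sex-swap symmetry the tests assert).

## Equilibria and stability

Interior fixed points are found numerically. `interior_equilibrium` is a
single-start Newton-type solve on the free coordinates `(p11, p22)` with a
retry ladder (caller seed, Hardy–Weinberg seeds across the frequency range,
and iteration-polished variants); `find_equilibria` is the exhaustive
multi-start search (21×21 simplex grid plus Hardy–Weinberg curve seeds,
deduplicated at 1e-8), which also reports the two fixation states. A point
is accepted as a fixed point at residual 1e-10 and counted interior when
all three genotype frequencies exceed 1e-10.

Stability is read off the spectral radius of a central-difference Jacobian
(step 1e-6) of the `(p11, p22)` update map; `stable` means radius `< 1 −
1e-9`. At fixation states a central difference would straddle the simplex
boundary and hit the defensive clipping, so the Jacobian there is evaluated
at a point nudged 1e-4 into the interior; this reproduces the analytic
rare-allele invasion eigenvalue (1.00278 at `s=0.1, α=1`) and classifies
fixations correctly on both sides of the stability envelope.

Closed forms for the additive random-mating case: equilibrium frequency
`p̂A1 = ½ − (1−α)/(2sα)` and the envelope `1/(1+s) < α < 1/(1−s)`. The
dominance rule "stable iff `hf + hm ≤ 1`" (at `α = 1`) is implemented as
stated but is exact only in the weak-selection limit: at `s = 0.1` the
numeric Jacobian — confirmed by 50,000-step iteration from perturbed
starts — places the true boundary near `hf + hm ≈ 1.04`. The rule is a
correct sufficient condition throughout; the acceptance test documents the
narrow finite-`s` band where rule and exact classification differ.

## Divergence and load statistics

* `male_female_fst`: `(pm−pf)² / (4 (p11+p12/2)(p22+p12/2))`; the
  denominator is the total heterozygosity `4pq` of the pooled genotype
  pool. For simulated populations the denominator uses the adult (pooled)
  genotype frequencies and `pf, pm` the adult per-sex frequencies.
* `fis`: `p12 / (2 pq) − 1`. Sign convention: heterozygote *excess* is
  positive (the negative of the classical `1 − Hobs/Hexp`), matching the
  biology here — opposed selection purges heterozygotes within each sex,
  so reproduction rebuilds an excess among zygotes.
* `load`: `1 − (w̄m + w̄f)/2` with `w̄` the genotype-frequency-weighted mean
  viability; each sex's best genotype has viability one, so this is the
  average per-sex shortfall from the optimum. At the symmetric additive
  equilibrium it reduces to `s/2` exactly.
* `weir_cockerham_fst`: the 1984 variance-components estimator with the
  sampled alleles as units (`θ̂ = a/(a+b)`; the within-individual component
  is zero for allele-count data). At equal per-sex sample sizes this is
  algebraically identical to Hudson's estimator, which the package also
  provides as a cross-check. Monomorphic samples yield NaN and are
  excluded from all distribution summaries.

Note the deterministic factor-of-two: the population formula divides by
`4pq` while the Hudson/W–C denominator is `p1(1−q2)+p2(1−q1) ≈ 2pq`, so
per-locus W–C estimates are about twice the population-formula values with
the same relative spread.

## Stochastic single-locus simulator

Finite-population counterpart of the recursion: per generation, (i) each
individual survives a Bernoulli trial at its sex-genotype viability
(implemented as per-class binomials, which is distributionally identical);
(ii) the surviving female × male genotype frequency outer product is
weighted elementwise by `M` and normalized into a mate-pair distribution;
(iii) `pairs` mating pairs are sampled with replacement (default
`pairs = N`), each contributing one offspring by independent choice of one
allele per parent; (iv) offspring sex is a fair Bernoulli. One offspring
per sampled pair with `pairs = N` reproduces multinomial Wright–Fisher
reproduction. A replicate in which one sex dies out is flagged extinct
and frozen, not an error. All replicates advance in lock-step through
vectorized numpy sampling; identical config + seed gives identical output.

## Genome-wide simulator (the synthetic-data generator)

Emulates the study scenario: `K = 10,000` diploids, 100 Mb of continuous
coordinate space (infinite sites, no reference sequence), per-nucleotide
recombination `1e-8` (one expected crossover per gamete) and mutation
`1e-10` (0.01 expected new mutations per gamete), 1,000 overlapping-
generation time steps, five replicates per scenario. Every mutation is
sexually antagonistic: a favored sex is chosen fairly; each sex's
magnitude is an independent half-Gaussian draw of scale 0.01, signed `+`
in the favored sex and `−` in the other; dominance is uniform on [0, 1]
per sex, independently. The neutral control runs the identical mutational
process with all selection coefficients forced to zero. Fitness is
multiplicative across loci with per-locus genotype fitnesses
`(1, 1+hs, 1+s)`.

Population regulation (the one part of the scenario the source text does
not fully specify): each step, Poisson(K) offspring are produced by
sampling random mother–father pairs from current adults; then every
individual — adult or newborn — survives with probability
`min(1, w·K/N)` where `N` is the pre-survival census. This keeps the
census fluctuating around `K`; late in antagonistic runs, accumulated
balanced polymorphisms raise mean absolute fitness above one and the
census rides ~15–25% above `K`. This regulation is a reconstruction, and
the genome-scale summary statistics carry correspondingly wide
uncertainty.

Implementation: haplotypes are stored sparsely (CSR rows of carried locus
ids, ordered by genomic position) because a haplotype carries ~30
mutations while ~1,800 loci segregate; gamete formation and fitness are
numba kernels that merge the parent's two sorted rows while walking the
gamete's crossover breakpoints. Dense reference implementations of both
kernels are kept and cross-checked in the tests. Loci lost from the
population are pruned each step; fixed loci are folded into per-sex
baseline fitness constants. A full antagonistic replicate runs in ~15 s
on one CPU.

### Genome-wide load

The single-locus load formula assumes the optimal genotype is attainable.
Genome-wide, three naive extensions fail: normalizing each locus by its
best genotype counts an unattainable optimum at every rare mutation
(~1,800 segregating loci drive the load to ~1 regardless of biology);
comparing with the mutation-free baseline nets out to ~0 because balanced
antagonistic loci sit at effective heterozygote advantage; and normalizing
by the fittest realized individual measures the population's fitness
variance rather than the cost of antagonism. The package therefore
reports, as its genome-wide load, the multiplicative aggregation of the
per-locus single-locus load across the **intermediate-frequency class**
(derived-allele frequency above `balanced_threshold`, default 0.10 — the
same class used for the balanced-polymorphism counts): these are the loci
whose both homozygotes are realized in the population and which the
antagonistic scenario specifically maintains; each contributes ≈ `s/2`
per sex, consistent with the deterministic equilibrium result. The value
is threshold-dependent (≈0.36 / 0.23 / 0.13 at thresholds 0.05 / 0.10 /
0.20 in a typical antagonistic run), which is disclosed here and exposed
as a config parameter; the fittest-realized-individual alternative is
retained in `ReplicateResult.fitness_summary["load_realized"]`. The load
trajectory uses a Hardy–Weinberg approximation of genotype frequencies;
the final-state value uses exact genotype counts.

## Subsampling analysis

`subsample_fst` draws `n` individuals per sex without replacement (or,
with `randomize_sex`, ignoring the recorded sex) and computes per-locus
FST from sample frequencies with either the population formula or the
Weir–Cockerham estimator; loci monomorphic in a draw are dropped, not
zero-filled, matching SNP-wise empirical practice. Under neutrality the
mean of the population-formula estimate equals the binomial sampling
floor `1/(4n)` (delta-method; verified for n ∈ {25, 50, 250}): 0.005 at
50 per sex and 0.01 at 25 per sex — orders of magnitude above the true
whole-population divergence of ~5×10⁻⁵, and uncorrelated with it.
Correlations between whole-population and subsampled per-locus FST are
Pearson, computed on single draws (as an empirical study would have);
100 draws per design is the default for distribution summaries.

## What the synthetic data do and do not show

The generator reproduces the mechanistic ingredients the analysis needs —
sex-opposed selection, linkage, drift, overlapping generations, and
realistic mutation/recombination supply — but not features of real data:
no neutral linked variation (every mutation is antagonistic by
construction), no genotyping error, no read misalignment from sex
chromosomes, no population structure or admixture, and no sex-ratio
skew. Passing tests therefore demonstrate the internal consistency of the
model and the sampling-variance mechanism, not that any particular
empirical male–female FST value is noise; the bioinformatic confounders
listed above are out of scope.

## Numerical choices

* Frequency-sum tolerance 1e-12 with defensive renormalization each step.
* Fixed-point residual 1e-10; interior threshold 1e-10; dedup 1e-8.
* Jacobian step 1e-6 (central), stability margin 1e-9.
* Equilibrium scans seed the solver at the closed-form Hardy–Weinberg
  point when it is interior.
* All TSV output is written at full double precision (`%.17g`) because
  quantities of interest span 1e-5 to 0.7.
* Every stochastic component draws from `numpy.random.Generator` seeded
  via `SeedSequence` spawning from a single root seed; replicates are
  exchangeable and individually reproducible.
* Acceptance-scale problem sizes: the genome scenario runs its full five
  replicates per arm at `K = 10,000` and 1,000 steps (the sparse engine
  makes this a few minutes); the single-locus check uses 200 replicates
  of `N = 20,000` over 50 generations; subsampling uses 40 draws per
  design per replicate population.

## Known limitations

* The population-regulation scheme is a reconstruction; census level and
  turnover rate (hence effective population size per step) may differ
  from the original scenario, which mostly affects the segregating-site
  count (order 1,500–1,900 here) and the dispersion of genome-scale
  summaries.
* The genome-wide load is definitionally threshold-dependent (above).
* The dominance stability rule is the weak-selection boundary; the exact
  boundary at moderate `s` sits slightly above `hf + hm = 1`.
* Extreme neutral per-locus FST is a maximum over thousands of χ²-like
  statistics: its position relative to any fixed round threshold (e.g.
  0.001) varies between runs at the study scale.
* Second-order approximations to the stability envelope are not
  implemented; only the exact bounds are exposed.
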