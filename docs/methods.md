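# Methods

`erparallel` simulates replicated Evolve-and-Resequence (E&R) selection
experiments on standing variation and implements the statistics used to ask
whether the replicated response is more parallel than drift and independent
per-locus selection can explain — and, if so, how strong the synergistic
(positive) epistasis among the selected alleles must be.

## The generative model

**Genetic architecture.** A set of `L` biallelic loci (haplotype-block
alleles), each with a starting frequency `p0` of the rising allele and a
selection coefficient `s >= 0`.  The default generator emulates the study
system (a copepod salinity-selection experiment): `L = 121` block alleles,
`p0 ~ Beta` with mean 0.29 and SD 0.09, truncated to (0.05, 0.95), and
`s ~ Gamma` with shape 4 and mean 0.133.  The Beta SD was derived once from
the printed range of starting frequencies (~0.10–0.47 ≈ mean ± 2 SD); the
Gamma shape was chosen once so the expected maximum of 121 draws matches the
printed maximum coefficient (~0.37).  `p0` and `s` are drawn independently;
the empirical architecture may contain dependence between them that the
generator does not reproduce (see Limitations).  Blocks are spread roughly
evenly (round-robin, jittered gaps) across a four-scaffold genome of 518 Mb,
the printed assembly size, giving a mean inter-block spacing of ~4.3 Mb; an
SNP-level mode groups ~41 SNPs per block.

**Wright-Fisher engine.** Diploid, discrete non-overlapping generations,
constant size `N` (default `Ne = 1750`).  Populations are initialized at
Hardy–Weinberg and linkage equilibrium from `p0`.  Each offspring draws two
parents with probability proportional to fitness (with replacement, selfing
permitted); each gamete recombines the parent's haplotypes — freely in
unlinked mode, or with crossover probabilities from physical distance at
1.6 cM/Mb through the Haldane map in linked mode.  For unlinked loci the
engine runs on genotype state only (a gamete carries the rising allele with
probability 0, 1/2, 1 given the parent's genotype), which is exactly
equivalent and considerably faster.  No mutation or migration: adaptation is
from standing variation only.

**Fitness models.**  With dominance weights `h_i ∈ {0, 1/2, 1}` for 0/1/2
copies and phenotype

```
x = Σ_i h_i s_i / Σ_i s_i ∈ [0, 1],
```

the six fitness functions are

| kind | w(genotype) |
|---|---|
| multiplicative | `Π_i (1 + h_i s_i)` |
| positive/negative epistasis | `Π_i (1 + h_i s_i) · exp(α (x − δ)²)`, α > 0 / α < 0 |
| shifted optimum | `exp(−((x − δ) − μ)² / σ²)` |
| directional | `(1 + s_q exp(r((x − δ) + b)))^(−1/s_q)`, r < 0 |
| truncating | `max{0, 1 − exp(−a((x − δ) + b))}` |

The phenotype is deliberately the normalized weighted **sum** of dosages: on
an equal-effect architecture evaluated haploid-style it reduces to `x = n/N`,
so the epistatic model collapses to `(1+s)^n · exp(α (n/N)²)` and the
marginal benefit of one more beneficial allele is
`(1+s)·exp(α(2n−1)/N²)` — increasing in `n` for α > 0, which is the
operational definition of synergy here.  (A product form of the phenotype
would be degenerate: any absent allele would force `x = 0` and break this
reduction.)  The multiplicative product is evaluated in log space so large
locus counts cannot overflow.

`δ` ("horizontal shift") is the difference between the mean initial
phenotype of a modified run (e.g. all loci at `p0 = 0.5`, or a locus
subsample) and that of the baseline architecture; subtracting it evaluates
the fitness shape at matched phenotypes, so comparisons isolate the shape of
the function rather than the placement of the initial phenotype
distribution.

**Quantitative-genetic parameters.** The study states calibration rules but
not values, so the package reconstructs them from the rules: the truncating
threshold culls ~25% of the founding population (`b = −(m + z_0.25·σ_x)`
with `m, σ_x` the mean and SD of the initial phenotype); benefits saturate
within ~4 initial-phenotype SD (`a = 3/(4σ_x)`); the directional model uses
the same scale (`s_q = 1, r = −a`); the optimum sits where the phenotype
distribution arrives by generation ten (`μ = m + 0.128`, the printed mean
frequency rise), with the Gaussian's maximum slope matched to the
directional model's (`σ = 4√(2/e)/a`).  These are reconstructions, not the
study's exact values.

**Observation (Pool-seq).** At each sampled generation (0, 6, 10), a pool of
`pool_n` individuals (default 100 in simulation) is drawn without
replacement; read counts are Binomial(coverage, pool frequency) with
coverage drawn uniformly on [10, 200] (the empirical coverage bounds; the
empirical shape between them is not published, so uniform is the default and
the sampler is pluggable).  Two independent generation-0 samples of the
founding population are emitted, mirroring the duplicate baseline
sequencing; analyses use their mean as the baseline frequency.  The
effective number of allele copies `N_eff = 2nc/(2n + c)` combines pool size
and coverage and serves as the regression weight.  Two of the ten treatment
lines, chosen uniformly at random, lack the final-generation sample
(emulating line extinction); generation-ten statistics run on the eight
survivors.

## Detecting selected alleles

Per line and timepoint, an allele is called selected when its observed
frequency increase over the baseline exceeds the 99.9th percentile of
10,000 neutral WF iterations at its starting frequency — one-sided, since
alleles are polarized to rise.  Neutral references are frequency-level
binomial chains (exact for a neutral unlinked locus); by default they
contain no observation noise, and the **final-generation** (generation-ten)
quantile is applied at every timepoint, both matching the study's stated
procedure.  Per-generation thresholds and observation-noise-inclusive
thresholds are options.

Parallelism is summarized by the pairwise Jaccard index `|A∩B|/|A∪B|` of
per-line selected-allele sets (mean over unordered pairs of surviving
lines; a pair of empty sets contributes 0 and is flagged) and by the
replicate frequency spectrum (RFS): per allele, the fraction of surviving
lines calling it.  Model comparison uses the empirical p-value of an
observed mean Jaccard within an ensemble (default 1000 iterations in the
study; the package's tests use 100, which puts the Monte Carlo SE of the
ensemble mean near 0.002, well below every tolerance tested).

## Per-locus tests and selection coefficients

**Drift-adjusted CMH / chi-square.** For each line and post-baseline
timepoint, the 2×2 table (baseline vs timepoint counts) contributes
`a_k − E_k` with the usual hypergeometric expectation; the statistic is
`U²/Var(U)` against χ²(1).  `Var(U)` inflates each stratum's hypergeometric
variance with the drift variance `p(1−p)[1−(1−1/(2Ne))^t]` and the
pool-stage sampling variance, and adds within-line covariance across
timepoints (shared drift up to the earlier timepoint, shared pool-stage and
read-stage baseline noise).  With `Ne = ∞` and no pool correction the
statistic is exactly the classical CMH statistic.  Exact equivalence with
any particular published implementation is not claimed; the design target
is calibration, and under the neutral null at `Ne = 1750` with full
observation noise the empirical type-I error at nominal 0.05 is ~0.06
(tested to stay within [0.03, 0.07]).  The single-line chi-square test is
the same construction restricted to one line.

**Treatment-vs-control LMM.** Response `y = arcsin√p_t − arcsin√p_0` per
line and post-baseline generation, weights ∝ `N_eff`, line as a random
intercept.  The likelihood-ratio test compares `y ~ generation + (1|line)`
against `y ~ generation * treatment + (1|line)` (χ², df = number of added
fixed effects; 2 for two timepoints).  Fits are maximum likelihood — not
REML — so the LRT on fixed effects is valid.  Because statsmodels' mixed
models do not accept known residual-variance ratios (observation weights),
the fitter is a small dedicated one: the likelihood is profiled over the
fixed effects and the residual variance, leaving a 1-D bounded search over
the variance ratio, with per-group rank-one Woodbury algebra; it reproduces
`lme4::lmer(..., weights=w, REML=FALSE)` to ~7 digits on fixture data.
At the experiment's size (10–14 lines × 2 timepoints) the ML LRT is mildly
anticonservative (mean statistic ~2.3 vs 2; type-I ~0.07 at 0.05), a
finite-sample property of the test itself that q-value correction sits on
top of.

**Selection coefficients.** `estimate_s` regresses the logit of the
(clamped) allele frequency on generation, either with a line random
intercept and `N_eff` weights or as averaged per-line weighted
least-squares slopes (the two variants correlate at r ≈ 0.99 on simulated
data).  The raw slope is returned by default; for data generated under the
`1, 1+hs, 1+s` fitness parameterization the slope equals
`log((1+s)/(1+hs))`, and `slope_to_s` (or `dominance=0.5`) inverts this to
recover the generating `s` (e.g. `s = 0.133` is recovered within ~5% on
noisy study-scale simulations).  Frequencies are clamped to
`[1/(2N_eff+2), 1 − 1/(2N_eff+2)]` before the logit; loci fixed at 0 or 1
in every sample return a flagged missing value.

**Multiple testing** uses Benjamini–Hochberg throughout (the π₀-adaptive
q-value of the original analysis is strictly less conservative; BH keeps
the package dependency-free and the difference is immaterial for the
simulated designs).

## ABC estimation of α

The epistasis strength is estimated from the target pair (mean Jaccard at
generations six and ten) by an adaptive population Monte Carlo scheme in
the style of Lenormand: `n` particles from the uniform prior [0, 50]; keep
the best 50% by Euclidean distance (the two summaries share units and
range, so no rescaling); iteratively resample survivors by weight, perturb
with a Gaussian kernel of variance twice the weighted survivor variance
(reflected at the prior bounds), re-score, merge and re-select, with
Beaumont-style importance weights; stop when fewer than 5% of survivors are
newly proposed particles.  The point estimate is the weighted posterior
mean; a weighted resample of configurable size summarizes the posterior.
Simulator failures reject the particle with a warning; a plain
rejection-ABC fallback cross-checks the sequential scheme.  Each particle
evaluates one simulated experiment ensemble by default (configurable); the
parameter-recovery test at the study scale retrieves a known α = 20 within
the 90% credible interval using 48 particles.

## Numerical and implementation choices

- Genotypes are uint8 arrays batched over populations; ensembles are
  simulated in chunks capped at ~4·10⁷ genotype entries to bound temporary
  arrays.  All randomness flows through a single `numpy` Generator per run;
  stage seeds are spawned from the run seed, so every output is
  reproducible bit-for-bit given the seed.
- Fitness is computed in log space and rescaled per population before
  parent sampling (fitness is only defined up to a constant within a
  population); exponent overflow raises instead of silently saturating.
- A population whose total fitness reaches zero (possible under the
  truncating model) raises an extinction error naming the line.
- Test problem sizes: ensembles of 100 iterations for study-scale Jaccard
  comparisons, 60 per quantitative-genetic model, 4000–10,000 loci for test
  calibration, 5000 replicate populations for drift-law checks.  These are
  the package's chosen sizes; they put Monte Carlo error well below each
  tolerance asserted.

## What the generator does and does not emulate

It emulates: the replication design (10 + 4 lines, duplicate baseline, two
extinctions), HWE/linkage-equilibrium founding, drift at `Ne = 1750`,
two-stage Pool-seq noise with bounded coverage, and block-level selected
alleles with printed-summary-calibrated effect and frequency
distributions.  It does **not** emulate: overlapping generations (the study
population was undisturbed; its own simulations also used discrete
generations), the empirical coverage distribution's shape, block
frequencies as medians over constituent SNPs, environmental shifts shared
within a line, or any dependence between `p0` and `s`.  Consequently,
passing ensemble-level checks shows the machinery reproduces the *model
mechanisms* (epistasis raising parallelism, locus-count and
starting-frequency effects, small linkage effects) at the study scale; the
absolute ensemble values under a given fitness model depend on the exact
per-block architecture, and with the reconstructed architecture the
multiplicative-model ensemble sits noticeably above the study's printed
means (~0.50/0.68 vs 0.33/0.52 at generations six/ten) while the
positive-epistasis and quantitative-genetic ensembles land close to theirs.

## Known limitations

- The weighted LMM models only sampling noise in its weights; drift makes
  it mildly anticonservative at `Ne = 1750` (documented above).
- The drift-adjusted CMH treats lines as sharing no baseline sample; data
  re-using one baseline across lines add a small cross-line covariance the
  statistic ignores (the simulated calling pipeline gives each line its own
  baseline rows from the duplicate founding samples).
- ABC identifiability of α degrades where mean Jaccard saturates in α;
  posterior intervals are honest about this (they widen).
- SNP-level simulations place SNPs on blocks but do not model
  ascertainment of blocks from SNP clustering.
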