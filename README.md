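# erparallel

Simulation and inference of **parallel polygenic adaptation** in replicated
Evolve-and-Resequence (E&R) experiments.

When independent populations adapt to the same environmental challenge from
shared standing variation, how often do the *same* alleles respond?  Under
the standard population-genetic model — each beneficial allele multiplying
fitness by its own factor `1 + h s` — replicate lines diverge through drift
and sampling, and the overlap of their selected-allele sets has a definite
null expectation.  Observed overlaps far above that expectation point to a
mechanism coupling the alleles, such as synergistic (positive) epistasis,
where fitness carries an extra factor

```
w = Π_i (1 + h_i s_i) · exp(α (x − δ)²),        x = Σ_i h_i s_i / Σ_i s_i,
```

so the marginal benefit of one more beneficial allele,
`(1+s)·exp(α(2n−1)/N²)` on an equal-effect architecture, grows with the
number `n` already carried.  `erparallel` implements this machinery
end-to-end for a copepod salinity-selection experiment design (121
haplotype-block alleles, 10 treatment + 4 control lines, generations
0/6/10, Pool-seq observation, `Ne ≈ 1750`):

- **`architecture` / `synth`** — genetic architectures calibrated to the
  study's printed summaries, and full synthetic E&R experiments
  (count + coverage tables, duplicate baseline samples, line extinction);
- **`wf`** — a vectorized diploid Wright–Fisher engine (six fitness models,
  optional physical linkage at 1.6 cM/Mb via the Haldane map) and neutral
  reference simulations;
- **`observe`** — the two-stage Pool-seq observation model (pool
  subsampling + read sampling), `N_eff` weights, TSV and sync-format I/O;
- **`inference`** — neutral-quantile selection calling (99.9th percentile),
  drift/Pool-seq-adjusted CMH and per-line chi-square tests, a weighted
  mixed-model treatment-vs-control LRT, logit-slope selection-coefficient
  estimation, BH correction;
- **`parallelism`** — pairwise Jaccard index, replicate frequency spectrum,
  empirical p-values, parallelism-vs-locus-count scans;
- **`abc_alpha`** — sequential (population Monte Carlo) ABC estimation of
  the epistasis strength α from mean-Jaccard summaries;
- **`pipeline` / `cli`** — an end-to-end, seed-reproducible pipeline with a
  thin `erparallel` command-line wrapper.

It is aimed at population geneticists exploring how epistasis, genetic
architecture, starting frequencies, and linkage shape the repeatability of
polygenic adaptation — and at anyone who wants a transparent, tested
re-implementation of this analysis chain on synthetic or tabulated
allele-frequency data.  See `docs/methods.md` for the full model
description and its assumptions.

## Worked example

One synthetic experiment under positive epistasis (α = 36.5), analysed
end-to-end, plus a 30-iteration model ensemble:

```python
from erparallel.pipeline import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(
    seed=11, outdir="demo_run",
    model_kind="positive_epistasis", alpha=36.5,
    parallelism_iterations=30,
))
```

prints (from `demo_run/summary.json`):

```json
{
  "ensemble_mean_jaccard": {"6": 0.639317, "10": 0.751424},
  "extinct_lines": ["T2", "T9"],
  "parallelism": {
    "6":  {"mean_jaccard": 0.638793, "mean_selected_per_line": 89.8},
    "10": {"mean_jaccard": 0.755329, "mean_selected_per_line": 101.125}
  },
  "tests": {"cmh_drift": 116, "lmm_treatment": 76},
  "mean_s_hat_slope": 0.203288
}
```

Reading this: in the simulated experiment each of the ten lines (eight
surviving at generation ten — `T2` and `T9` went extinct) shows significant
frequency shifts for ~90 of the 121 selected alleles at generation six and
~101 at generation ten; the mean pairwise Jaccard overlap of those
selected-allele sets is 0.64 and 0.76.  The 30-iteration ensemble puts the
model's expected overlap at 0.64/0.75, so this realization is typical.  Of
121 loci, 116 reach q < 0.05 under the drift-adjusted CMH test and 76 under
the more conservative treatment-vs-control mixed-model LRT; the mean logit
slope (0.20 per generation) reflects both the per-locus coefficients and
the epistatic acceleration.  The same run under `model_kind=
"multiplicative"` gives ensemble overlaps near 0.50/0.68 — the separation
between the two models at matched architectures is the signal the ABC
stage (`erparallel abc`, or `RunConfig(abc_enabled=True)`) inverts to
estimate α.

The same pipeline is scriptable from the shell:

```bash
erparallel run-all --seed 11 --outdir demo_run --model positive_epistasis \
    --alpha 36.5 --iterations 30
```

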