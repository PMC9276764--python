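"""Parallelism statistics and ensemble simulation of the experiment.

Parallelism between replicate lines is summarized as (1) the pairwise
Jaccard index of the per-line sets of selected alleles and (2) the replicate
frequency spectrum (RFS): for each allele, the fraction of surviving lines
in which it was called.  ``simulate_parallelism`` runs the full generative
chain -- replicate WF lines, Pool-seq observation, neutral-quantile calling,
random line extinction -- for an ensemble of experiment iterations and
returns the per-iteration mean Jaccard index per generation, the quantity
compared between fitness models and matched by ABC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import Architecture, ExperimentDesign
from .fitness import FitnessModel, delta_for
from .observe import uniform_coverage
from .wf import NeutralQuantiles, neutral_quantiles, simulate_batch


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|; defined as 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class ParallelismSummary:
    jaccard_matrix: np.ndarray  # (n_lines, n_lines), diagonal 1
    mean_jaccard: float
    rfs: np.ndarray  # per-allele proportion of lines with a significant shift
    generation: int
    lines: list
    locus_ids: list
    has_empty_sets: bool = False


def _pairwise_mean_jaccard(calls_bool: np.ndarray):
    """calls_bool: (n_lines, L) boolean. Returns (J matrix, mean over pairs)."""
    c = calls_bool.astype(np.float64)
    inter = c @ c.T
    sizes = c.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(J, 1.0)
    n = c.shape[0]
    iu = np.triu_indices(n, k=1)
    return J, float(J[iu].mean()) if iu[0].size else float("nan")


def parallelism_summary(calls, generation: int) -> ParallelismSummary:
    """Pairwise Jaccard matrix, mean Jaccard and RFS at one generation,
    over the lines present at that generation (surviving lines)."""
    lines = calls.lines(generation)
    if len(lines) < 2:
        raise ValueError("need >= 2 surviving lines at the generation")
    sub = calls.calls[calls.calls["generation"] == generation]
    piv = sub.pivot_table(index="line", columns="locus_id", values="call",
                          aggfunc="first").loc[lines]
    mat = piv.to_numpy(dtype=bool)
    J, meanJ = _pairwise_mean_jaccard(mat)
    rfs = mat.mean(axis=0)
    return ParallelismSummary(
        jaccard_matrix=J,
        mean_jaccard=meanJ,
        rfs=rfs,
        generation=generation,
        lines=lines,
        locus_ids=list(piv.columns),
        has_empty_sets=bool((mat.sum(axis=1) == 0).any()),
    )


def empirical_pvalue(observed_mean_j, simulated_mean_js, alternative="two_sided"):
    """Empirical p-value of an observed statistic against simulations.

    two_sided: 2 * min(frac(sim >= obs), frac(sim <= obs)), capped at 1.
    """
    sims = np.asarray(simulated_mean_js, dtype=float)
    if sims.size < 100:
        raise ValueError("need >= 100 simulation iterations")
    ge = np.mean(sims >= observed_mean_j)
    le = np.mean(sims <= observed_mean_j)
    if alternative == "greater":
        return float(ge)
    if alternative == "less":
        return float(le)
    return float(min(1.0, 2.0 * min(ge, le)))


# ---------------------------------------------------------------------------
# ensemble simulation
# ---------------------------------------------------------------------------


def default_thresholds(
    arch: Architecture,
    design: ExperimentDesign,
    n_iter: int = 10_000,
    q: float = 0.999,
    seed=0,
    with_observation: bool = False,
) -> NeutralQuantiles:
    """Neutral-simulation thresholds for each locus's starting frequency at
    every post-baseline sampled generation."""
    gens = [g for g in design.sampled_generations if g > 0]
    kwargs = {}
    if with_observation:
        kwargs = dict(
            pool_n=design.pool_n_individuals,
            coverage_sampler=uniform_coverage(design.coverage_min, design.coverage_max),
        )
    return neutral_quantiles(
        arch.p0, design.Ne, gens, n_iter=n_iter, q=q, seed=seed, **kwargs
    )


def simulate_parallelism(
    arch: Architecture,
    design: ExperimentDesign,
    model: FitnessModel | None,
    n_iter: int,
    seed,
    thresholds: NeutralQuantiles | None = None,
    baseline_arch: Architecture | None = None,
    return_rfs: bool = False,
    threshold_generation: int | str = "final",
):
    """Ensemble of synthetic experiments; per-iteration mean Jaccard index.

    Each iteration simulates the treatment lines (control lines play no role
    in the Jaccard statistic), observes them through the Pool-seq layer,
    calls selected alleles against the neutral thresholds using the mean of
    two duplicate generation-0 samples as the baseline frequency, removes
    ``design.n_extinct_at_final`` random lines from the final generation, and
    computes the mean pairwise Jaccard index per generation over surviving
    lines.

    With ``baseline_arch`` set and a phenotype-dependent model, the
    horizontal shift delta is set so initial phenotypes match the baseline
    architecture.  Returns a DataFrame (iteration, generation, mean_jaccard)
    or (df, rfs DataFrame) if ``return_rfs``.
    """
    rng = np.random.default_rng(seed)
    if thresholds is None:
        thresholds = default_thresholds(
            arch, design, seed=rng.integers(2**31)
        )
    if baseline_arch is not None and model is not None and model.uses_phenotype:
        model = model.with_delta(model.delta + delta_for(arch, baseline_arch))
    gens = [g for g in design.sampled_generations if g > 0]
    L = arch.n_loci
    n_lines = design.n_treatment_lines
    # per-locus thresholds aligned with arch order; by default (mirroring the
    # calling procedure of the experiment) the final-generation neutral
    # quantile is applied at every timepoint
    k_of = np.abs(arch.p0[:, None] - thresholds.p0[None, :]).argmin(axis=1)
    if threshold_generation == "per_generation":
        tgens = gens
    elif threshold_generation == "final":
        tgens = [design.final_generation] * len(gens)
    else:
        tgens = [int(threshold_generation)] * len(gens)
    jcols = [int(np.nonzero(thresholds.generations == g)[0][0]) for g in tgens]
    thr = thresholds.thresholds[np.ix_(k_of, jcols)]  # (L, T)

    B = n_iter * n_lines
    _, pools = simulate_batch(
        arch, model, design.Ne, B, gens, rng, pool_n=design.pool_n_individuals
    )
    qpool = pools.reshape(n_iter, n_lines, len(gens), L) / (
        2.0 * design.pool_n_individuals
    )
    sampler = uniform_coverage(design.coverage_min, design.coverage_max)
    cov = sampler(qpool.shape, rng)
    obs = rng.binomial(cov, qpool) / cov

    # duplicate baseline samples of the shared founding population
    qb = rng.binomial(2 * design.pool_n_individuals, arch.p0, size=(n_iter, 2, L)) / (
        2.0 * design.pool_n_individuals
    )
    covb = sampler(qb.shape, rng)
    p0_hat = (rng.binomial(covb, qb) / covb).mean(axis=1)  # (n_iter, L)

    calls = obs - p0_hat[:, None, None, :] > thr.T[None, None, :, :]

    final = design.final_generation
    records = []
    rfs_acc = {g: np.zeros(L) for g in gens} if return_rfs else None
    rfs_n = {g: 0 for g in gens} if return_rfs else None
    for it in range(n_iter):
        surviving = np.arange(n_lines)
        extinct = (
            rng.choice(n_lines, size=design.n_extinct_at_final, replace=False)
            if design.n_extinct_at_final
            else np.array([], dtype=int)
        )
        for j, g in enumerate(gens):
            rows = (
                np.setdiff1d(surviving, extinct) if g == final else surviving
            )
            mat = calls[it, rows, j]
            _, meanJ = _pairwise_mean_jaccard(mat)
            records.append((it, g, meanJ))
            if return_rfs:
                rfs_acc[g] += mat.mean(axis=0)
                rfs_n[g] += 1
    df = pd.DataFrame(records, columns=["iteration", "generation", "mean_jaccard"])
    if return_rfs:
        rfs = pd.DataFrame(
            {g: rfs_acc[g] / max(1, rfs_n[g]) for g in gens},
            index=arch.locus_ids,
        )
        return df, rfs
    return df


def parallelism_vs_nloci(
    arch: Architecture,
    design: ExperimentDesign,
    model: FitnessModel | None,
    nloci_grid,
    n_iter: int = 100,
    seed=0,
    thresholds: NeutralQuantiles | None = None,
) -> pd.DataFrame:
    """Mean Jaccard index as a function of the number of contributing loci.

    For each grid value, loci are randomly subsampled from the architecture,
    the horizontal shift delta realigns the initial phenotype distribution
    with the full architecture, and the ensemble is re-simulated.  Returns
    per grid value the mean and interquartile range of the per-iteration
    mean Jaccard at the final generation.
    """
    rng = np.random.default_rng(seed)
    if thresholds is None:
        thresholds = default_thresholds(arch, design, seed=rng.integers(2**31))
    final = design.final_generation
    rows = []
    for n in nloci_grid:
        if n > arch.n_loci:
            raise ValueError("grid value exceeds the number of available loci")
        sub = arch.subsample(int(n), seed=int(rng.integers(2**31)))
        df = simulate_parallelism(
            sub,
            design,
            model,
            n_iter=n_iter,
            seed=int(rng.integers(2**31)),
            thresholds=thresholds,
            baseline_arch=arch,
        )
        vals = df[df["generation"] == final]["mean_jaccard"]
        rows.append(
            (int(n), vals.mean(), vals.quantile(0.25), vals.quantile(0.75))
        )
    return pd.DataFrame(rows, columns=["n_loci", "mean_jaccard", "q25", "q75"])
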