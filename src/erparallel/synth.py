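"""Synthetic E&R experiments emulating the study design.

``gen_experiment`` wires together the WF engine and the Pool-seq observation
layer: treatment lines evolve under the supplied fitness model, control lines
under neutrality, and every sample is reported as allele counts at sampled
read coverage.  Two independent generation-0 samples of the shared founding
population are emitted (the study sequenced the starting culture twice), and
a configurable number of randomly chosen treatment lines go extinct before
the final generation and lack a final-generation sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import Architecture, ExperimentDesign
from .fitness import FitnessModel
from .observe import sample_reads, uniform_coverage
from .wf import ExtinctionError, simulate_batch


def _sample_rows(arch, line, flag, gen, alt, cov, pool_n):
    return pd.DataFrame(
        {
            "line": line,
            "treatment_flag": flag,
            "generation": gen,
            "locus_id": arch.locus_ids,
            "block_id": arch.block_ids,
            "alt_count": alt,
            "coverage": cov,
            "pool_n": pool_n,
            "freq": alt / cov,
        }
    )


def baseline_samples(
    arch: Architecture, design: ExperimentDesign, rng: np.random.Generator, n_samples: int = 2
):
    """Duplicate Pool-seq samples of the shared founding population.

    The founding culture is large relative to one pool, so the pool stage is
    binomial on 2*pool_n allele copies at the architecture frequencies,
    followed by read sampling.
    """
    sampler = uniform_coverage(design.coverage_min, design.coverage_max)
    out = []
    for _ in range(n_samples):
        qpool = rng.binomial(2 * design.pool_n_individuals, arch.p0) / (
            2.0 * design.pool_n_individuals
        )
        out.append(sample_reads(qpool, sampler, rng))
    return out


def gen_experiment(
    arch: Architecture,
    design: ExperimentDesign,
    model: FitnessModel | None,
    seed,
) -> pd.DataFrame:
    """Simulate a full synthetic E&R experiment; returns a trajectory table.

    Treatment lines are named T1..Tn, control lines C1..Cn; the duplicate
    generation-0 samples appear as lines S1 and S2 (treatment_flag 0).
    Extinct treatment lines (chosen uniformly at random) have no
    final-generation sample.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    gens = [g for g in design.sampled_generations if g > 0]
    sampler = uniform_coverage(design.coverage_min, design.coverage_max)
    frames = []

    for k, (alt, cov) in enumerate(baseline_samples(arch, design, rng)):
        frames.append(
            _sample_rows(arch, f"S{k + 1}", 0, 0, alt, cov, design.pool_n_individuals)
        )

    def _observe_lines(model_, n_lines, prefix, flag):
        try:
            _, pools = simulate_batch(
                arch,
                model_,
                design.Ne,
                n_lines,
                gens,
                rng,
                pool_n=design.pool_n_individuals,
            )
        except ExtinctionError as exc:
            raise ExtinctionError(
                f"line {prefix}{(exc.population_index or 0) + 1} went extinct",
                line=f"{prefix}{(exc.population_index or 0) + 1}",
            ) from exc
        qpool = pools / (2.0 * design.pool_n_individuals)
        for i in range(n_lines):
            for j, g in enumerate(gens):
                alt, cov = sample_reads(qpool[i, j], sampler, rng)
                frames.append(
                    _sample_rows(
                        arch, f"{prefix}{i + 1}", flag, g, alt, cov,
                        design.pool_n_individuals,
                    )
                )

    _observe_lines(model, design.n_treatment_lines, "T", 1)
    _observe_lines(None, design.n_control_lines, "C", 0)

    traj = pd.concat(frames, ignore_index=True)
    if design.n_extinct_at_final > 0:
        extinct = rng.choice(
            design.n_treatment_lines, size=design.n_extinct_at_final, replace=False
        )
        extinct_lines = {f"T{i + 1}" for i in extinct}
        drop = traj["line"].isin(extinct_lines) & (
            traj["generation"] == design.final_generation
        )
        traj = traj.loc[~drop].reset_index(drop=True)
        traj.attrs["extinct_lines"] = sorted(extinct_lines)
    return traj


def attach_baseline(traj: pd.DataFrame) -> pd.DataFrame:
    """Add per-line generation-0 rows using the mean of the duplicate
    founding-population samples (as done when analysing the experiment)."""
    base = traj[traj["generation"] == 0]
    if base.empty:
        raise ValueError("trajectory table has no generation-0 samples")
    agg = base.groupby("locus_id", sort=False).agg(
        alt_count=("alt_count", "mean"),
        coverage=("coverage", "mean"),
        pool_n=("pool_n", "sum"),
        block_id=("block_id", "first"),
    )
    frames = [traj]
    for line, sub in traj[traj["generation"] > 0].groupby("line"):
        flag = int(sub["treatment_flag"].iloc[0])
        loci = sub["locus_id"].drop_duplicates()
        a = agg.loc[loci]
        frames.append(
            pd.DataFrame(
                {
                    "line": line,
                    "treatment_flag": flag,
                    "generation": 0,
                    "locus_id": loci.to_numpy(),
                    "block_id": a["block_id"].to_numpy(),
                    "alt_count": a["alt_count"].to_numpy(),
                    "coverage": a["coverage"].to_numpy(),
                    "pool_n": a["pool_n"].to_numpy(),
                    "freq": (a["alt_count"] / a["coverage"]).to_numpy(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs.update(traj.attrs)
    return out
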