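"""End-to-end orchestration: synthesize -> simulate -> observe -> call ->
summarize -> (optionally) ABC, with per-stage derived seeds and file outputs.

Every stochastic stage receives its own sub-seed spawned from the run seed,
so runs are deterministic and stages can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .architecture import (
    Architecture,
    ConfigurationError,
    ExperimentDesign,
    gen_architecture,
)
from .fitness import FitnessModel, KINDS, QT_KINDS, reconstruct_qt_params
from .inference import (
    call_selected,
    cmh_drift_test,
    estimate_s,
    lmm_treatment_test,
    traj_to_count_arrays,
)
from .observe import write_trajectory_tsv
from .parallelism import default_thresholds, parallelism_summary, simulate_parallelism
from .synth import attach_baseline, gen_experiment

logger = logging.getLogger("erparallel")


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "erparallel_run"
    # architecture: generated unless a TSV path is given
    arch_tsv: str | None = None
    n_loci: int = 121
    linkage_mode: str = "unlinked"
    level: str = "block"
    # fitness model
    model_kind: str = "multiplicative"
    alpha: float = 0.0
    # design overrides
    design: dict = field(default_factory=dict)
    # analysis switches
    neutral_iterations: int = 10_000
    call_quantile: float = 0.999
    q_value_cutoff: float = 0.05
    run_tests: tuple = ("cmh", "lmm", "s")
    parallelism_iterations: int = 0  # model-ensemble iterations (0 = skip)
    # ABC
    abc_enabled: bool = False
    abc_prior: tuple = (0.0, 50.0)
    abc_particles: int = 50
    abc_sim_iterations: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def build_model(self, arch: Architecture) -> FitnessModel | None:
        kind = self.model_kind
        if kind in ("neutral", "none"):
            return None
        if kind not in KINDS:
            raise ConfigurationError(f"unknown fitness model kind {kind!r}")
        if kind in QT_KINDS:
            return reconstruct_qt_params(arch, kind)
        return FitnessModel(kind=kind, alpha=self.alpha)


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns the machine-readable summary
    (also written to ``<outdir>/summary.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("arch", "experiment", "neutral", "parallelism", "abc"), ss.spawn(5)
        )
    }
    logger.info("stage seeds: %s", seeds)
    summary: dict = {"seed": config.seed, "stage_seeds": seeds}

    # --- architecture ------------------------------------------------------
    if config.arch_tsv:
        arch = Architecture.from_tsv(config.arch_tsv, linkage_mode=config.linkage_mode)
    else:
        arch = gen_architecture(
            config.n_loci,
            level=config.level,
            seed=seeds["arch"],
            linkage_mode=config.linkage_mode,
        )
    arch.to_tsv(out / "architecture.tsv")
    design = ExperimentDesign(**config.design)
    model = config.build_model(arch)  # validates before any simulation
    summary["n_loci"] = arch.n_loci
    summary["model"] = config.model_kind

    # --- experiment --------------------------------------------------------
    traj = gen_experiment(arch, design, model, seed=seeds["experiment"])
    write_trajectory_tsv(traj, out / "trajectories.tsv")
    summary["extinct_lines"] = traj.attrs.get("extinct_lines", [])

    # --- neutral thresholds and calls -------------------------------------
    nq = default_thresholds(
        arch, design, n_iter=config.neutral_iterations,
        q=config.call_quantile, seed=seeds["neutral"],
    )
    nq.to_tsv(out / "neutral_thresholds.tsv")
    calls = call_selected(traj, nq, p0_ref=arch.p0)
    calls.calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    summary["parallelism"] = {}
    for g in design.sampled_generations:
        if g == 0:
            continue
        psum = parallelism_summary(calls, g)
        summary["parallelism"][str(g)] = {
            "mean_jaccard": round(psum.mean_jaccard, 6),
            "mean_selected_per_line": round(
                float(np.asarray(psum.rfs).sum()), 3
            ),
            "rfs_mean": round(float(np.mean(psum.rfs)), 6),
        }
        pd.DataFrame({"locus_id": psum.locus_ids, "rfs": psum.rfs}).to_csv(
            out / f"rfs_gen{g}.tsv", sep="\t", index=False
        )

    # --- per-locus tests ---------------------------------------------------
    results = []
    traj_b = attach_baseline(traj)
    if "cmh" in config.run_tests:
        alt, cov, gens, _, loci = traj_to_count_arrays(traj_b, treatment_flag=1)
        results.append(
            cmh_drift_test(alt, cov, gens, design.Ne,
                           pool_n=design.pool_n_individuals, locus_ids=loci)
        )
    if "lmm" in config.run_tests:
        results.append(lmm_treatment_test(traj_b))
    if results:
        tests = pd.concat(results)
        tests.to_csv(out / "tests.tsv", sep="\t")
        summary["tests"] = {
            name: int((sub["q_value"] < config.q_value_cutoff).sum())
            for name, sub in tests.groupby("test_name")
        }
    if "s" in config.run_tests:
        shat = estimate_s(traj_b, use_random_line_effect=True)
        shat.to_csv(out / "selection_coefficients.tsv", sep="\t")
        summary["mean_s_hat_slope"] = round(float(shat["s_hat"].mean()), 6)

    # --- model-ensemble parallelism ---------------------------------------
    if config.parallelism_iterations:
        ens = simulate_parallelism(
            arch, design, model, n_iter=config.parallelism_iterations,
            seed=seeds["parallelism"], thresholds=nq,
        )
        ens.to_csv(out / "parallelism_ensemble.tsv", sep="\t", index=False)
        summary["ensemble_mean_jaccard"] = {
            str(g): round(float(sub["mean_jaccard"].mean()), 6)
            for g, sub in ens.groupby("generation")
        }

    # --- ABC ---------------------------------------------------------------
    if config.abc_enabled:
        from .abc_alpha import abc_estimate_alpha

        final = design.final_generation
        mid = [g for g in design.sampled_generations if 0 < g < final]
        target = [
            summary["parallelism"][str(g)]["mean_jaccard"] for g in (*mid, final)
        ]

        def sim(alpha_val, rng):
            m = (
                FitnessModel(kind="positive_epistasis", alpha=alpha_val)
                if alpha_val > 0
                else FitnessModel(kind="multiplicative")
            )
            df = simulate_parallelism(
                arch, design, m, n_iter=config.abc_sim_iterations,
                seed=int(rng.integers(2**31)), thresholds=nq,
            )
            return df.groupby("generation")["mean_jaccard"].mean().to_numpy()

        res = abc_estimate_alpha(
            target, sim, prior=tuple(config.abc_prior),
            n_particles=config.abc_particles, seed=seeds["abc"],
        )
        pd.DataFrame(
            {"alpha": res.posterior_alphas, "weight": res.weights}
        ).to_csv(out / "abc_posterior.tsv", sep="\t", index=False)
        summary["abc"] = {
            "alpha_hat": round(res.point_estimate, 4),
            "ci90": [round(v, 4) for v in res.credible_interval(0.9)],
            "n_simulations": res.n_simulations,
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
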