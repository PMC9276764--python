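"""Wright-Fisher engine: initialization, drift, selection, neutral quantiles."""

import numpy as np
import pytest
from scipy import stats

from erparallel.architecture import ExperimentDesign, gen_architecture
from erparallel.fitness import FitnessModel
from erparallel.wf import (
    ExtinctionError,
    initialize_population,
    neutral_quantiles,
    run_replicates,
    simulate_batch,
    step_generation,
)


def point_arch(n, p0, s, **kw):
    return gen_architecture(
        n, freq_dist=("point", p0), s_dist=("point", s), seed=0, **kw
    )


class TestInitialization:
    def test_boundary_frequency(self):
        arch = point_arch(1, 1 - 1e-12, 0.1)
        pop = initialize_population(arch, 100, seed=0)
        assert np.all(pop.genotypes == 2)

    def test_hwe_proportions(self):
        arch = point_arch(1, 0.5, 0.1)
        pop = initialize_population(arch, 100_000, seed=1)
        g = pop.genotypes[:, 0]
        p = pop.allele_frequencies()[0]
        se_p = np.sqrt(0.25 / (2 * pop.N))
        assert abs(p - 0.5) < 3 * se_p
        for k, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
            se = np.sqrt(expected * (1 - expected) / pop.N)
            assert abs(np.mean(g == k) - expected) < 3 * se

    def test_linkage_equilibrium_at_start(self):
        arch = point_arch(2, 0.5, 0.1)
        pop = initialize_population(arch, 10_000, seed=2)
        r = np.corrcoef(pop.genotypes.T)[0, 1]
        assert abs(r) < 0.02


class TestDriftAndSelection:
    def test_neutral_drift_variance_matches_wf_law(self):
        # Var(p_t - p_0) = E[p0 q0] (1 - (1 - 1/(2N))^t); the generation-0
        # HWE draw is itself a sampling event, so the change from the
        # realized starting frequency is the quantity obeying the law
        arch = point_arch(1, 0.3, 0.0)
        rng = np.random.default_rng(5)
        N, t, B = 100, 5, 5000
        freqs, _ = simulate_batch(arch, None, N, B, [0, t], rng)
        d = freqs[:, 1, 0] - freqs[:, 0, 0]
        expected = 0.3 * 0.7 * (1 - 1 / (2 * N)) * (1 - (1 - 1 / (2 * N)) ** t)
        assert d.mean() == pytest.approx(0.0, abs=3 * d.std() / np.sqrt(B))
        assert d.var() == pytest.approx(expected, rel=0.10)

    def test_deterministic_selection_recursion(self):
        # one generation at huge N matches the exact diploid recursion with
        # fitnesses 1, 1+s/2, 1+s
        p, s = 0.2, 0.1
        arch = point_arch(1, p, s)
        wbar = p * p * (1 + s) + 2 * p * (1 - p) * (1 + s / 2) + (1 - p) ** 2
        p_exp = (p * p * (1 + s) + p * (1 - p) * (1 + s / 2)) / wbar
        rng = np.random.default_rng(6)
        freqs, _ = simulate_batch(
            arch, FitnessModel(kind="multiplicative"), 1_000_000, 1, [1], rng
        )
        se = np.sqrt(p_exp * (1 - p_exp) / 2e6)
        assert freqs[0, 0, 0] == pytest.approx(p_exp, abs=3.5 * se)

    def test_heterozygosity_decay(self):
        arch = point_arch(1, 0.5, 0.0)
        rng = np.random.default_rng(7)
        N, t, B = 50, 10, 5000
        freqs, _ = simulate_batch(arch, None, N, B, [t], rng)
        het = 2 * freqs[:, 0, 0] * (1 - freqs[:, 0, 0])
        # t WF generations plus the initialization draw
        expected = 0.5 * (1 - 1 / (2 * N)) ** (t + 1)
        assert het.mean() == pytest.approx(expected, rel=0.05)

    def test_synergy_fixes_more_alleles(self):
        # paired ensembles: positive epistasis fixes at least as many
        # beneficial alleles by generation 10 as the multiplicative model
        arch = gen_architecture(20, seed=8)
        rng0, rng1 = np.random.default_rng(9), np.random.default_rng(9)
        f0, _ = simulate_batch(
            arch, FitnessModel(kind="multiplicative"), 200, 200, [10], rng0
        )
        f1, _ = simulate_batch(
            arch, FitnessModel(kind="positive_epistasis", alpha=36.5), 200, 200,
            [10], rng1,
        )
        assert (f1[:, 0] == 1.0).mean() >= (f0[:, 0] == 1.0).mean()

    def test_frequencies_bounded_and_absorbing(self):
        arch = point_arch(2, 0.05, 0.0)
        rng = np.random.default_rng(10)
        freqs, _ = simulate_batch(arch, None, 30, 200, [5, 10], rng)
        assert np.all((freqs >= 0) & (freqs <= 1))
        lost = freqs[:, 0, :] == 0.0
        assert np.all(freqs[:, 1, :][lost] == 0.0)  # loss is absorbing

    def test_extinction_error(self):
        arch = point_arch(1, 0.3, 0.1)
        # truncating model with an unreachable threshold kills everyone
        m = FitnessModel(kind="truncating", a_tr=5.0, b_tr=-2.0)
        pop = initialize_population(arch, 50, seed=0)
        with pytest.raises(ExtinctionError):
            step_generation(pop, m, seed_state=1)


class TestStepGeneration:
    def test_population_size_constant(self):
        arch = gen_architecture(5, seed=1)
        pop = initialize_population(arch, 200, seed=0)
        nxt = step_generation(pop, FitnessModel(kind="multiplicative"), 3)
        assert nxt.N == 200 and nxt.generation == 1

    def test_deterministic_given_seed(self):
        arch = gen_architecture(5, seed=1)
        pop = initialize_population(arch, 100, seed=0)
        a = step_generation(pop, None, 3)
        b = step_generation(pop, None, 3)
        np.testing.assert_array_equal(a.h1, b.h1)
        np.testing.assert_array_equal(a.h2, b.h2)


class TestRunReplicates:
    def test_independent_lines_and_determinism(self):
        arch = gen_architecture(40, seed=2)
        design = ExperimentDesign(Ne=200, n_treatment_lines=6, n_extinct_at_final=0)
        t1 = run_replicates(arch, design, None, 6, seed=4)
        t2 = run_replicates(arch, design, None, 6, seed=4)
        assert t1.equals(t2)
        final = t1[t1["generation"] == 10].pivot_table(
            index="line", columns="locus_id", values="freq"
        )
        # neutral lines drift independently: per-locus frequency *changes*
        # are uncorrelated across lines (raw frequencies share the p0 layout)
        import pandas as pd

        p0 = pd.Series(arch.p0, index=arch.locus_ids)
        delta = final.to_numpy() - p0.loc[final.columns].to_numpy()
        corr = np.corrcoef(delta)
        off = corr[np.triu_indices(6, 1)]
        assert np.nanmean(np.abs(off)) < 0.35

    def test_selected_allele_rise_in_sanity_corridor(self, arch121, design):
        traj = run_replicates(
            arch121, design, FitnessModel(kind="multiplicative"), 4, seed=5
        )
        start = traj[traj["generation"] == 0].groupby("locus_id")["freq"].mean()
        end = traj[traj["generation"] == 10].groupby("locus_id")["freq"].mean()
        rise = (end - start).mean()
        assert 0.05 < rise < 0.25


class TestLinkage:
    def test_linked_converges_to_unlinked_at_large_distance(self):
        # loci >= 50 cM apart assort essentially freely: paired ensembles of
        # final frequencies agree in distribution (mean and variance)
        from dataclasses import replace

        from erparallel.architecture import Architecture, Locus

        # 12 loci, 32 Mb apart (~51 cM at 1.6 cM/Mb) on one scaffold
        loci = tuple(
            Locus(f"l{i}", f"b{i}", "s1", i * 32_000_000, s=0.15, p0=0.3)
            for i in range(12)
        )
        arch_u = Architecture(loci=loci, linkage_mode="unlinked")
        arch_l = Architecture(loci=loci, linkage_mode="linked")
        m = FitnessModel(kind="multiplicative")
        fu, _ = simulate_batch(arch_u, m, 300, 150, [10], np.random.default_rng(1))
        fl, _ = simulate_batch(arch_l, m, 300, 150, [10], np.random.default_rng(1))
        assert fu.mean() == pytest.approx(fl.mean(), abs=0.01)
        assert fu.std() == pytest.approx(fl.std(), rel=0.1)

    def test_gamete_masks_respect_map_distance(self):
        # adjacent loci 1 kb apart almost never recombine: the inheritance
        # mask is constant along the chromosome; at 50 Mb it is ~independent
        from erparallel.architecture import Architecture, Locus
        from erparallel.wf import _gamete_masks

        rng = np.random.default_rng(2)
        for gap in (1_000, 50_000_000):
            loci = tuple(
                Locus(f"l{i}", f"b{i}", "s1", i * gap, s=0.0, p0=0.5)
                for i in range(2)
            )
            arch = Architecture(loci=loci, linkage_mode="linked")
            m = _gamete_masks(arch, 1, 20_000, rng)[0]
            frac = np.mean(m[:, 0] == m[:, 1])
            assert frac == pytest.approx(1.0 - arch.crossover_probs()[1], abs=0.02)
        # and each locus' marginal is a fair coin
        assert m.mean(axis=0) == pytest.approx([0.5, 0.5], abs=0.02)


class TestNeutralQuantiles:
    def test_matches_diffusion_oracle(self):
        nq = neutral_quantiles([0.286], 1750, [10], n_iter=10_000, seed=3)
        z = stats.norm.ppf(0.999)
        oracle = z * np.sqrt(0.286 * 0.714 * (1 - (1 - 1 / 3500) ** 10))
        assert nq.thresholds[0, 0] == pytest.approx(oracle, rel=0.15)

    def test_vanishes_at_huge_ne(self):
        nq = neutral_quantiles([0.3], 10**8, [10], n_iter=1000, seed=4)
        assert nq.thresholds[0, 0] < 0.005

    def test_median_drift_is_zero(self):
        nq = neutral_quantiles([0.4], 1750, [10], n_iter=10_000, q=0.5, seed=5)
        assert abs(nq.thresholds[0, 0]) < 0.01

    def test_monotone_in_generation(self):
        nq = neutral_quantiles([0.2, 0.4], 500, [2, 6, 10], n_iter=5000, seed=6)
        assert np.all(np.diff(nq.thresholds, axis=1) >= 0)

    def test_observation_layer_raises_thresholds(self):
        from erparallel.observe import uniform_coverage

        plain = neutral_quantiles([0.3], 1750, [10], n_iter=5000, seed=7)
        noisy = neutral_quantiles(
            [0.3], 1750, [10], n_iter=5000, seed=7, pool_n=100,
            coverage_sampler=uniform_coverage(10, 200),
        )
        assert noisy.thresholds[0, 0] > plain.thresholds[0, 0]

    def test_tsv_round_trip(self, tmp_path):
        from erparallel.wf import NeutralQuantiles

        nq = neutral_quantiles([0.2, 0.3], 500, [6, 10], n_iter=1000, seed=8)
        nq.to_tsv(tmp_path / "nq.tsv")
        back = NeutralQuantiles.from_tsv(tmp_path / "nq.tsv")
        np.testing.assert_allclose(back.thresholds, nq.thresholds, rtol=1e-6)
        assert back.threshold(0.2, 6) == pytest.approx(nq.threshold(0.2, 6), rel=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            neutral_quantiles([0.3], 500, [10], n_iter=10)
        with pytest.raises(ValueError):
            neutral_quantiles([0.3], 500, [10], q=1.5)
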