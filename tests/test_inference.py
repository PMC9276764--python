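"""Selection inference: calling, s estimation, count tests, LMM, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from erparallel.architecture import ExperimentDesign, gen_architecture
from erparallel.fitness import FitnessModel
from erparallel.inference import (
    call_selected,
    chisq_line_test,
    cmh_drift_test,
    estimate_s,
    fdr_adjust,
    lmm_treatment_test,
    slope_to_s,
)
from erparallel.lmm import fit_weighted_lmm
from erparallel.synth import attach_baseline, gen_experiment
from erparallel.wf import NeutralQuantiles, neutral_quantiles


def _traj_from_freqs(freqs_by_line, generations, coverage=1000, pool_n=500, flag=1):
    """Build a noise-free trajectory table from {line: [p per generation]}."""
    rows = []
    for line, ps in freqs_by_line.items():
        for g, p in zip(generations, ps):
            rows.append(
                dict(line=line, treatment_flag=flag, generation=g, locus_id="L0",
                     block_id="B0", alt_count=p * coverage, coverage=coverage,
                     pool_n=pool_n, freq=p)
            )
    return pd.DataFrame(rows)


class TestCallSelected:
    def make_nq(self):
        return NeutralQuantiles(
            p0=np.array([0.3]), generations=np.array([6, 10]),
            thresholds=np.array([[0.05, 0.075]]), n_iterations=1000, Ne=1750,
            q=0.999,
        )

    def test_flat_trajectories_zero_calls(self):
        traj = _traj_from_freqs({"S1": [0.3], "T1": [0.3, 0.3]}, [0, 6, 10])
        traj.loc[traj["line"] == "T1", "generation"] = [6, 10]
        calls = call_selected(traj, self.make_nq())
        assert not calls.calls["call"].any()

    def test_large_rise_called(self):
        rows = _traj_from_freqs({"S1": [0.3]}, [0])
        t = _traj_from_freqs({"T1": [0.5, 0.8]}, [6, 10])
        calls = call_selected(pd.concat([rows, t]), self.make_nq())
        assert calls.calls["call"].all()
        assert calls.selected_set("T1", 10) == {"L0"}

    def test_threshold_convention_final_generation(self):
        # a +0.06 shift at generation six clears the gen-6 quantile (0.05)
        # but not the default (final-generation, 0.075) threshold
        rows = pd.concat(
            [_traj_from_freqs({"S1": [0.3]}, [0]),
             _traj_from_freqs({"T1": [0.36, 0.36]}, [6, 10])]
        )
        strict = call_selected(rows, self.make_nq())
        assert not strict.calls["call"].any()
        lenient = call_selected(rows, self.make_nq(),
                                threshold_generation="per_generation")
        assert lenient.selected_set("T1", 6) == {"L0"}
        assert lenient.selected_set("T1", 10) == set()

    def test_missing_threshold_generation_raises(self):
        rows = pd.concat(
            [_traj_from_freqs({"S1": [0.3]}, [0]),
             _traj_from_freqs({"T1": [0.5]}, [7])]
        )
        with pytest.raises(KeyError):
            call_selected(rows, self.make_nq(), threshold_generation="per_generation")


class TestEstimateS:
    def test_noiseless_logistic_recovers_slope_exactly(self):
        s, p0 = 0.15, 0.2
        t = np.array([0, 6, 10])
        p = p0 * np.exp(s * t) / (1 - p0 + p0 * np.exp(s * t))
        traj = _traj_from_freqs({"T1": p, "T2": p}, t)
        for mixed in (True, False):
            res = estimate_s(traj, use_random_line_effect=mixed)
            assert res["s_hat"].iloc[0] == pytest.approx(s, abs=1e-6)

    def test_flat_trajectory_zero(self):
        traj = _traj_from_freqs({"T1": [0.4, 0.4, 0.4], "T2": [0.4, 0.4, 0.4]},
                                [0, 6, 10])
        res = estimate_s(traj)
        assert res["s_hat"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_fixed_frequencies_flagged_missing(self):
        traj = _traj_from_freqs({"T1": [1.0, 1.0, 1.0], "T2": [1.0, 1.0, 1.0]},
                                [0, 6, 10])
        res = estimate_s(traj)
        assert np.isnan(res["s_hat"].iloc[0])

    def test_timepoint_shift_invariance(self):
        # slope depends only on spacing, not on the labels' origin
        s, p0 = 0.1, 0.3
        t = np.array([0, 6, 10])
        p = p0 * np.exp(s * t) / (1 - p0 + p0 * np.exp(s * t))
        t1 = _traj_from_freqs({"T1": p, "T2": p}, t)
        t2 = _traj_from_freqs({"T1": p, "T2": p}, t + 5)
        t2g = t2.copy()
        t2g.loc[t2g["generation"] == 5, "generation"] = 0  # keep a baseline row
        r1 = estimate_s(t1)["s_hat"].iloc[0]
        t2b = _traj_from_freqs({"T1": p, "T2": p}, [0, 6, 10])
        r2 = estimate_s(t2b)["s_hat"].iloc[0]
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_dominance_inversion(self):
        # slope log((1+s)/(1+s/2)) maps back to s under codominance
        s = 0.2
        slope = np.log((1 + s) / (1 + s / 2))
        assert slope_to_s(slope, h=0.5) == pytest.approx(s, rel=1e-9)

    def test_wf_recovery_and_variant_agreement(self):
        # generating coefficient 0.133 (fitnesses 1, 1+s/2, 1+s) recovered
        # within 15% by the dominance-corrected estimator; the mixed and
        # per-line variants agree strongly
        arch = gen_architecture(
            40, freq_dist=("point", 0.29), s_dist=("point", 0.133), seed=0
        )
        design = ExperimentDesign(
            n_treatment_lines=8, n_control_lines=2, n_extinct_at_final=0
        )
        ests, r1all, r2all = [], [], []
        for rep in range(4):
            traj = attach_baseline(
                gen_experiment(arch, design, FitnessModel(kind="multiplicative"),
                               seed=100 + rep)
            )
            ests.append(estimate_s(traj, dominance=0.5)["s_hat"].to_numpy())
            r1all.append(estimate_s(traj, True)["s_hat"].to_numpy())
            r2all.append(estimate_s(traj, False)["s_hat"].to_numpy())
        mean_hat = np.nanmean(np.concatenate(ests))
        assert abs(mean_hat - 0.133) / 0.133 < 0.15
        r = stats.pearsonr(np.concatenate(r1all), np.concatenate(r2all))[0]
        assert r > 0.7


class TestWeightedLMM:
    def test_matches_lme4_ml_fit(self):
        # frozen oracle: the same data fitted in lme4 with
        # lmer(y ~ x + (1|g), weights=w, REML=FALSE)
        rng = np.random.default_rng(3)
        n_g, n_per = 8, 4
        g = np.repeat(np.arange(n_g), n_per)
        x = np.tile(np.arange(n_per, dtype=float), n_g)
        w = rng.uniform(0.5, 3.0, size=g.size)
        b = rng.normal(0, 0.5, n_g)
        y = 1.0 + 0.3 * x + b[g] + rng.normal(0, 0.4 / np.sqrt(w))
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_weighted_lmm(y, X, g, w)
        np.testing.assert_allclose(fit.beta, [0.8167367, 0.3385216], rtol=1e-5)
        assert fit.tau2 == pytest.approx(0.4357803, rel=1e-4)
        assert fit.sigma2 == pytest.approx(0.1777193, rel=1e-4)
        assert fit.loglik == pytest.approx(-22.69712, abs=1e-4)

    def test_boundary_tau_zero(self):
        rng = np.random.default_rng(4)
        g = np.repeat(np.arange(6), 5)
        x = np.tile(np.arange(5, dtype=float), 6)
        y = 2.0 - 0.1 * x + rng.normal(0, 0.3, g.size)  # no group effect
        fit = fit_weighted_lmm(y, np.column_stack([np.ones_like(x), x]), g,
                               np.ones_like(y))
        assert fit.tau2 < 0.02


class TestCountTests:
    @staticmethod
    def classical_cmh(alt, cov):
        a = alt[:, 1, :]
        c0, ct, x0 = cov[:, 0, :], cov[:, 1, :], alt[:, 0, :]
        T = c0 + ct
        m1 = x0 + a
        E = ct * m1 / T
        V = c0 * ct * m1 * (T - m1) / (T**2 * (T - 1))
        return (a - E).sum(0) ** 2 / V.sum(0)

    def test_reduces_to_classical_cmh(self):
        rng = np.random.default_rng(7)
        alt = rng.binomial(100, 0.3, size=(8, 2, 60)).astype(float)
        cov = np.full((8, 2, 60), 100.0)
        mine = cmh_drift_test(alt, cov, [0, 10], np.inf, pool_n=None)
        oracle = self.classical_cmh(alt, cov)
        np.testing.assert_allclose(mine["statistic"].to_numpy(), oracle, rtol=1e-6)

    def test_no_change_gives_null_pvalues(self):
        alt = np.full((4, 3, 5), 30.0)
        cov = np.full((4, 3, 5), 100.0)
        res = cmh_drift_test(alt, cov, [0, 6, 10], 1750, pool_n=100)
        assert (res["statistic"] < 1e-9).all()
        assert (res["p_value"] > 0.99).all()

    @staticmethod
    def _neutral_counts(rng, L, nl=8, Ne=1750, pool=100, gens=(0, 6, 10)):
        p0 = rng.uniform(0.1, 0.5, size=L)
        alt = np.empty((nl, len(gens), L))
        cov = np.empty_like(alt)
        for l in range(nl):
            p = p0.copy()
            prev = 0
            for j, g in enumerate(gens):
                for _ in range(g - prev):
                    p = rng.binomial(2 * Ne, p) / (2 * Ne)
                prev = g
                qp = rng.binomial(2 * pool, p) / (2 * pool)
                c = rng.integers(10, 201, size=L)
                alt[l, j] = rng.binomial(c, qp)
                cov[l, j] = c
        return alt, cov

    def test_type_one_error_calibrated_under_drift_null(self):
        rng = np.random.default_rng(11)
        alt, cov = self._neutral_counts(rng, 4000)
        res = cmh_drift_test(alt, cov, [0, 6, 10], 1750, pool_n=100)
        rate = (res["p_value"] < 0.05).mean()
        assert 0.03 < rate < 0.07
        r1 = chisq_line_test(alt[0], cov[0], [0, 6, 10], 1750, pool_n=100)
        rate1 = (r1["p_value"] < 0.05).mean()
        assert 0.03 < rate1 < 0.07

    def test_unadjusted_test_is_anticonservative_on_same_null(self):
        # without the drift/pool inflation the same data give a wildly
        # inflated false-positive rate -- the adjustment is doing the work
        rng = np.random.default_rng(12)
        alt, cov = self._neutral_counts(rng, 1000)
        res = cmh_drift_test(alt, cov, [0, 6, 10], np.inf, pool_n=None)
        assert (res["p_value"] < 0.05).mean() > 0.15

    def test_line_specific_deterministic_rise_significant(self):
        # s=0.3 deterministic rise over 10 generations at coverage 100
        p0, s = 0.3, 0.3
        p10 = p0 * (1 + s / 2) ** 10 / (1 - p0 + p0 * (1 + s / 2) ** 10)
        alt = np.array([[p0 * 100, p10 * 100]])[:, :, None]
        cov = np.full((1, 2, 1), 100.0)
        res = chisq_line_test(alt, cov, [0, 10], 1750, pool_n=100)
        assert res["p_value"].iloc[0] < 1e-3

    def test_needs_replicates(self):
        alt = np.full((1, 2, 3), 10.0)
        with pytest.raises(ValueError):
            cmh_drift_test(alt, alt + 10, [0, 10], 1750)
        with pytest.raises(ValueError):
            cmh_drift_test(np.full((3, 2, 3), 5.0), np.full((3, 2, 3), 10.0),
                           [0, 10], Ne=-5)


class TestLMMTreatmentTest:
    def _null_traj(self, seed, L=300, Ne=1750):
        arch = gen_architecture(L, seed=1)
        design = ExperimentDesign(
            Ne=Ne, n_treatment_lines=6, n_control_lines=4, n_extinct_at_final=0
        )
        return attach_baseline(gen_experiment(arch, design, None, seed=seed))

    def test_null_matches_chisq2(self):
        res = lmm_treatment_test(self._null_traj(42, L=400))
        lrt = res["statistic"].dropna().to_numpy()
        ks = stats.kstest(lrt, "chi2", args=(2,))
        assert ks.pvalue > 0.01
        assert (res["p_value"] < 0.05).mean() < 0.12

    def test_power_under_selection(self):
        arch = gen_architecture(
            150, freq_dist=("point", 0.3), s_dist=("point", 0.2), seed=2
        )
        design = ExperimentDesign(
            n_treatment_lines=8, n_control_lines=4, n_extinct_at_final=0
        )
        traj = attach_baseline(
            gen_experiment(arch, design, FitnessModel(kind="multiplicative"),
                           seed=77)
        )
        res = lmm_treatment_test(traj)
        assert (res["p_value"] < 0.05).mean() > 0.8

    def test_constant_frequencies_give_zero_lrt(self):
        rows = []
        for line, flag in [("T1", 1), ("T2", 1), ("C1", 0), ("C2", 0)]:
            for g in (0, 6, 10):
                rows.append(dict(line=line, treatment_flag=flag, generation=g,
                                 locus_id="L0", block_id="B0", alt_count=40,
                                 coverage=100, pool_n=50, freq=0.4))
        res = lmm_treatment_test(pd.DataFrame(rows))
        assert res["statistic"].iloc[0] == 0.0
        assert res["p_value"].iloc[0] == 1.0

    def test_requires_controls(self):
        rows = _traj_from_freqs({"T1": [0.3, 0.4, 0.5], "T2": [0.3, 0.4, 0.5]},
                                [0, 6, 10])
        with pytest.raises(ValueError):
            lmm_treatment_test(rows)


class TestFDR:
    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_bh_arithmetic(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_fdr_control_under_null(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=10_000)
        q = fdr_adjust(p)
        prop = (q < 0.05).mean()
        assert prop <= 0.05 * (1 + 3 * np.sqrt(0.05 * 0.95 / 10_000) / 0.05)
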