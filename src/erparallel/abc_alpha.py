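"""Sequential ABC estimation of the epistasis-strength parameter alpha.

Implements the adaptive population Monte Carlo scheme of Lenormand and
colleagues: an initial particle cloud from the uniform prior is iteratively
refined by resampling the best half, perturbing with a Gaussian kernel whose
variance is twice the weighted variance of the survivors, and re-scoring,
until fewer than a set proportion of newly proposed particles displace
survivors.  The posterior is the final weighted particle set; the point
estimate is its weighted mean.  A plain rejection-ABC fallback is provided
for cross-checking.

Distances are Euclidean on the summary-statistic vector, by default the
(mean Jaccard at generation six, mean Jaccard at generation ten) pair, which
shares units and range across components so no rescaling is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np


class ToleranceScheduleError(RuntimeError):
    """Every proposed particle failed; the tolerance schedule cannot proceed."""


@dataclass
class ABCResult:
    posterior_alphas: np.ndarray
    weights: np.ndarray  # normalized, sum to 1
    point_estimate: float
    prior: tuple[float, float]
    n_post_burnin: int
    target_stats: tuple
    n_simulations: int = 0
    n_steps: int = 0

    def posterior_sample(self, size: int | None = None, seed=0) -> np.ndarray:
        """Weighted resample of the posterior (size defaults to
        n_post_burnin)."""
        rng = np.random.default_rng(seed)
        size = size or self.n_post_burnin
        return rng.choice(self.posterior_alphas, size=size, p=self.weights)

    def credible_interval(self, level: float = 0.9) -> tuple[float, float]:
        order = np.argsort(self.posterior_alphas)
        a = self.posterior_alphas[order]
        cw = np.cumsum(self.weights[order])
        lo = float(np.interp((1 - level) / 2, cw, a))
        hi = float(np.interp(1 - (1 - level) / 2, cw, a))
        return lo, hi

    def weighted_sd(self) -> float:
        m = self.point_estimate
        return float(np.sqrt(np.sum(self.weights * (self.posterior_alphas - m) ** 2)))


def _score(simulator, alphas, target, rng, n_sims):
    """Distances of simulated summaries to the target; failed simulations get
    infinite distance (rejected with a warning)."""
    t = np.asarray(target, dtype=float)
    d = np.empty(len(alphas))
    for i, a in enumerate(alphas):
        try:
            s = np.asarray(simulator(float(a), rng), dtype=float)
            if not np.all(np.isfinite(s)):
                raise ValueError("non-finite summary statistics")
            d[i] = float(np.sqrt(((s - t) ** 2).sum()))
        except ToleranceScheduleError:
            raise
        except Exception as exc:  # noqa: BLE001 - simulator failures are data
            warnings.warn(f"simulator failed at alpha={a:.3g}: {exc}")
            d[i] = np.inf
        n_sims[0] += 1
    return d


def abc_estimate_alpha(
    target,
    simulator: Callable,
    prior: tuple[float, float] = (0.0, 50.0),
    n_particles: int = 100,
    n_post_burnin: int = 1000,
    seed=0,
    keep_fraction: float = 0.5,
    p_acc_min: float = 0.05,
    max_steps: int = 20,
) -> ABCResult:
    """Estimate alpha by sequential (Lenormand-style) ABC.

    ``simulator(alpha, rng)`` must return the summary-statistic vector for
    one simulated experiment ensemble at that alpha; ``target`` is the
    observed vector.  Deterministic given ``seed`` for a seed-respecting
    simulator.
    """
    lo, hi = map(float, prior)
    if not hi > lo:
        raise ValueError("invalid prior interval")
    target = np.asarray(target, dtype=float)
    if not np.all(np.isfinite(target)):
        raise ValueError("target statistics must be finite")
    rng = np.random.default_rng(seed)
    n_sims = [0]

    n_keep = max(2, int(np.ceil(keep_fraction * n_particles)))
    alphas = rng.uniform(lo, hi, size=n_particles)
    dists = _score(simulator, alphas, target, rng, n_sims)
    if not np.any(np.isfinite(dists)):
        raise ToleranceScheduleError("all initial particles failed")
    keep = np.argsort(dists)[:n_keep]
    alphas, dists = alphas[keep], dists[keep]
    weights = np.full(n_keep, 1.0 / n_keep)
    steps = 0
    for _ in range(max_steps):
        steps += 1
        var = np.sum(weights * (alphas - np.sum(weights * alphas)) ** 2)
        sd = np.sqrt(max(2.0 * var, 1e-12))
        n_new = n_particles - n_keep
        src = rng.choice(n_keep, size=n_new, p=weights)
        prop = alphas[src] + rng.normal(0.0, sd, size=n_new)
        # reflect proposals back into the prior support
        for _ in range(100):
            bad = (prop < lo) | (prop > hi)
            if not bad.any():
                break
            prop[bad] = np.where(prop[bad] < lo, 2 * lo - prop[bad], 2 * hi - prop[bad])
        prop = np.clip(prop, lo, hi)
        d_new = _score(simulator, prop, target, rng, n_sims)
        # Lenormand importance weights for the new particles
        dens = np.array(
            [
                np.sum(
                    weights
                    * np.exp(-0.5 * ((a - alphas) / sd) ** 2)
                    / (sd * np.sqrt(2 * np.pi))
                )
                for a in prop
            ]
        )
        w_new = np.where(dens > 0, 1.0 / (hi - lo) / np.maximum(dens, 1e-300), 0.0)
        all_a = np.concatenate([alphas, prop])
        all_d = np.concatenate([dists, d_new])
        all_w = np.concatenate([weights, w_new])
        if not np.any(np.isfinite(all_d)):
            raise ToleranceScheduleError("all particles rejected")
        keep = np.argsort(all_d)[:n_keep]
        p_acc = float(np.mean(keep >= n_keep))  # fraction of survivors that are new
        alphas, dists, weights = all_a[keep], all_d[keep], all_w[keep]
        if weights.sum() <= 0:
            weights = np.full(n_keep, 1.0 / n_keep)
        weights = weights / weights.sum()
        if p_acc < p_acc_min:
            break
    point = float(np.sum(weights * alphas))
    return ABCResult(
        posterior_alphas=alphas,
        weights=weights,
        point_estimate=point,
        prior=(lo, hi),
        n_post_burnin=n_post_burnin,
        target_stats=tuple(np.atleast_1d(target)),
        n_simulations=n_sims[0],
        n_steps=steps,
    )


def rejection_abc(
    target,
    simulator: Callable,
    prior: tuple[float, float] = (0.0, 50.0),
    n_draws: int = 1000,
    accept_fraction: float = 0.1,
    seed=0,
) -> ABCResult:
    """Plain rejection ABC cross-check: draw from the prior, keep the
    closest ``accept_fraction`` of particles with equal weights."""
    lo, hi = map(float, prior)
    rng = np.random.default_rng(seed)
    n_sims = [0]
    alphas = rng.uniform(lo, hi, size=n_draws)
    d = _score(simulator, alphas, np.asarray(target, float), rng, n_sims)
    n_keep = max(2, int(np.ceil(accept_fraction * n_draws)))
    keep = np.argsort(d)[:n_keep]
    w = np.full(n_keep, 1.0 / n_keep)
    return ABCResult(
        posterior_alphas=alphas[keep],
        weights=w,
        point_estimate=float(alphas[keep].mean()),
        prior=(lo, hi),
        n_post_burnin=n_keep,
        target_stats=tuple(np.atleast_1d(np.asarray(target, float))),
        n_simulations=n_sims[0],
        n_steps=1,
    )
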