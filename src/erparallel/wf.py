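"""Diploid Wright-Fisher forward engine with selection and optional linkage.

The engine tracks explicit haplotypes (two 0/1 arrays per individual) so that
recombination and genotype-dependent fitness are exact.  Reproduction is
standard WF: each of N offspring draws two parents with probability
proportional to fitness (with replacement, selfing permitted); each gamete is
formed by recombining the parent's haplotypes -- free recombination in
unlinked mode, or crossovers between adjacent loci with probabilities from
physical distance via the Haldane map in linked mode (loci on different
scaffolds assort independently).

All heavy routines are vectorized over a *batch* of independent populations
(replicate lines and/or simulation iterations), which is what makes
ensemble-level parallelism statistics affordable in pure numpy.

Neutral reference simulations (used for significance thresholds) run at the
frequency level as binomial chains, which is exactly the WF law for a neutral
unlinked locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .architecture import Architecture, ExperimentDesign
from .fitness import FitnessModel, POPGEN_KINDS, phenotype

_MAX_BATCH_ELEMS = 40_000_000  # cap B*N*L per chunk to bound temp arrays


class ExtinctionError(RuntimeError):
    """Total fitness of a population reached zero."""

    def __init__(self, msg: str, population_index: int | None = None, line: str | None = None):
        super().__init__(msg)
        self.population_index = population_index
        self.line = line


# ---------------------------------------------------------------------------
# batched core
# ---------------------------------------------------------------------------


def _hwe_init_batch(
    arch: Architecture, N: int, B: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Independent HWE draw per individual per locus (linkage equilibrium)."""
    p0 = arch.p0
    h1 = (rng.random((B, N, arch.n_loci), dtype=np.float32) < p0.astype(np.float32)).astype(np.uint8)
    h2 = (rng.random((B, N, arch.n_loci), dtype=np.float32) < p0.astype(np.float32)).astype(np.uint8)
    return h1, h2


def _batch_fitness(G: np.ndarray, arch: Architecture, model: FitnessModel) -> np.ndarray:
    """Fitness (B, N) for genotype copy-number array G (B, N, L), evaluated in
    log space and rescaled per population (fitness is only defined up to a
    constant within a population)."""
    Gf = G.astype(np.float32)
    s = arch.s
    if model.kind in POPGEN_KINDS:
        l_het = np.log1p(0.5 * s).astype(np.float32)
        l_hom = np.log1p(s).astype(np.float32)
        hom = 0.5 * (Gf * Gf - Gf)  # indicator of 2 copies, as float
        logw = np.einsum("bnl,l->bn", Gf, l_het) + np.einsum(
            "bnl,l->bn", hom, l_hom - 2.0 * l_het
        )
        logw = logw.astype(np.float64)
        if model.kind != "multiplicative":
            x = np.einsum("bnl,l->bn", Gf, (s / (2.0 * s.sum())).astype(np.float32))
            logw += model.alpha * (x.astype(np.float64) - model.delta) ** 2
        logw -= logw.max(axis=1, keepdims=True)
        return np.exp(logw)
    # quantitative-genetic kinds: fitness depends on the phenotype only
    x = np.einsum("bnl,l->bn", Gf, (s / (2.0 * s.sum())).astype(np.float32)).astype(
        np.float64
    )
    xs = x - model.delta
    if model.kind == "shifted_optimum":
        return np.exp(-((xs - model.mu) ** 2) / model.sigma**2)
    if model.kind == "directional":
        expo = np.clip(model.r * (xs + model.b_dir), None, 600.0)
        return np.exp(-np.log1p(model.s_q * np.exp(expo)) / model.s_q)
    # truncating
    return np.maximum(0.0, 1.0 - np.exp(-model.a_tr * (xs + model.b_tr)))


def _sample_parents(
    w: np.ndarray | None, B: int, N: int, rng: np.random.Generator
) -> np.ndarray:
    """Fitness-proportional parent indices, shape (B, 2N)."""
    if w is None:  # neutral: uniform parents
        return rng.integers(0, N, size=(B, 2 * N))
    cw = np.cumsum(w, axis=1)
    totals = cw[:, -1]
    dead = ~(totals > 0.0)
    if dead.any():
        raise ExtinctionError(
            "population fitness sum is zero", population_index=int(np.argmax(dead))
        )
    u = rng.random((B, 2 * N)) * totals[:, None]
    idx = np.empty((B, 2 * N), dtype=np.int64)
    for b in range(B):
        idx[b] = np.searchsorted(cw[b], u[b], side="right")
    return np.minimum(idx, N - 1)


def _gamete_masks(
    arch: Architecture, B: int, N: int, rng: np.random.Generator
) -> np.ndarray:
    """0/1 array (B, N, L): which parental haplotype contributes each locus."""
    L = arch.n_loci
    if arch.linkage_mode == "unlinked" or L == 1:
        return rng.integers(0, 2, size=(B, N, L), dtype=np.uint8)
    r = arch.crossover_probs().astype(np.float32)  # r[0] = 0.5: random start
    C = (rng.random((B, N, L), dtype=np.float32) < r).astype(np.uint8)
    return np.cumsum(C, axis=2, dtype=np.uint8) & np.uint8(1)


def _make_gametes(
    h1: np.ndarray,
    h2: np.ndarray,
    parent: np.ndarray,
    arch: Architecture,
    rng: np.random.Generator,
) -> np.ndarray:
    hp1 = _row_gather(h1, parent)
    hp2 = _row_gather(h2, parent)
    m = _gamete_masks(arch, h1.shape[0], h1.shape[1], rng)
    return np.where(m, hp1, hp2)


def _step_batch(
    h1: np.ndarray,
    h2: np.ndarray,
    arch: Architecture,
    model: FitnessModel | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    B, N, _ = h1.shape
    if model is None:
        w = None
    else:
        w = _batch_fitness(h1 + h2, arch, model)
    parents = _sample_parents(w, B, N, rng)
    new_h1 = _make_gametes(h1, h2, parents[:, :N], arch, rng)
    new_h2 = _make_gametes(h1, h2, parents[:, N:], arch, rng)
    return new_h1, new_h2


def _row_gather(a: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """a[(b, rows[b, n]), :] for each population b; faster than
    take_along_axis for whole-row gathers."""
    B, N, L = a.shape
    flat = a.reshape(B * N, L)
    idx = rows + (np.arange(B, dtype=rows.dtype) * N)[:, None]
    return flat[idx.ravel()].reshape(B, rows.shape[1], L)


def _step_batch_unlinked(
    G: np.ndarray,
    arch: Architecture,
    model: FitnessModel | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """One WF generation on genotype state only (valid for free
    recombination: a gamete carries the rising allele with probability 0,
    1/2 or 1 for parent genotypes 0, 1, 2, independently across loci)."""
    B, N, L = G.shape
    w = None if model is None else _batch_fitness(G, arch, model)
    parents = _sample_parents(w, B, N, rng)
    out = np.empty_like(G)
    Gm = _row_gather(G, parents[:, :N])
    coin = rng.integers(0, 2, size=(B, N, L), dtype=np.uint8)
    out[:] = (Gm >> 1) | (Gm & coin)
    Gp = _row_gather(G, parents[:, N:])
    coin = rng.integers(0, 2, size=(B, N, L), dtype=np.uint8)
    out += (Gp >> 1) | (Gp & coin)
    return out


def _pool_counts(
    G: np.ndarray, pool_n: int, rng: np.random.Generator
) -> np.ndarray:
    """Allele copies among pool_n individuals sampled without replacement from
    each population; shape (B, L)."""
    B, N, _ = G.shape
    if pool_n > N:
        raise ValueError("pool_n exceeds population size")
    order = rng.random((B, N)).argsort(axis=1)[:, :pool_n]
    return _row_gather(G, order).sum(axis=1, dtype=np.int64)


def simulate_batch(
    arch: Architecture,
    model: FitnessModel | None,
    N: int,
    B: int,
    record_generations: Sequence[int],
    rng: np.random.Generator,
    pool_n: int | None = None,
):
    """Evolve B independent populations of size N and record state.

    Returns (true_freqs, pool_counts) where true_freqs has shape
    (B, T, L) and pool_counts (B, T, L) (or None if pool_n is None).
    Populations are initialized with fresh HWE draws from ``arch``.
    """
    record = sorted(set(int(g) for g in record_generations))
    if record and record[0] < 0:
        raise ValueError("record generations must be >= 0")
    L = arch.n_loci
    max_chunk = max(1, _MAX_BATCH_ELEMS // max(1, N * L))
    freqs = np.empty((B, len(record), L), dtype=np.float64)
    pools = np.empty((B, len(record), L), dtype=np.int64) if pool_n else None
    t_final = record[-1] if record else 0
    unlinked = arch.linkage_mode == "unlinked"
    for start in range(0, B, max_chunk):
        stop = min(B, start + max_chunk)
        h1, h2 = _hwe_init_batch(arch, N, stop - start, rng)
        if unlinked:
            G = h1 + h2
            h1 = h2 = None
        j = 0
        for t in range(t_final + 1):
            if t > 0:
                if unlinked:
                    G = _step_batch_unlinked(G, arch, model, rng)
                else:
                    h1, h2 = _step_batch(h1, h2, arch, model, rng)
            if j < len(record) and t == record[j]:
                Gt = G if unlinked else h1 + h2
                freqs[start:stop, j] = Gt.sum(axis=1, dtype=np.int64) / (2.0 * N)
                if pools is not None:
                    pools[start:stop, j] = _pool_counts(Gt, pool_n, rng)
                j += 1
    return freqs, pools


# ---------------------------------------------------------------------------
# single-population API
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """One population: two haplotype arrays of shape (N, n_loci)."""

    h1: np.ndarray
    h2: np.ndarray
    generation: int
    arch: Architecture

    @property
    def N(self) -> int:
        return self.h1.shape[0]

    @property
    def genotypes(self) -> np.ndarray:
        """Copy-number matrix (N, n_loci), values in {0, 1, 2}."""
        return (self.h1 + self.h2).astype(np.int64)

    def allele_frequencies(self) -> np.ndarray:
        return self.genotypes.sum(axis=0) / (2.0 * self.N)

    def phenotypes(self) -> np.ndarray:
        return np.asarray(phenotype(self.genotypes, self.arch))


def initialize_population(arch: Architecture, N: int, seed) -> Population:
    """Fresh population at HWE with the architecture's starting frequencies."""
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)
    h1, h2 = _hwe_init_batch(arch, N, 1, rng)
    return Population(h1=h1[0], h2=h2[0], generation=0, arch=arch)


def step_generation(
    pop: Population, model: FitnessModel | None, seed_state
) -> Population:
    """One WF generation; ``seed_state`` is a Generator or seed."""
    rng = (
        seed_state
        if isinstance(seed_state, np.random.Generator)
        else np.random.default_rng(seed_state)
    )
    try:
        h1, h2 = _step_batch(pop.h1[None], pop.h2[None], pop.arch, model, rng)
    except ExtinctionError as exc:
        raise ExtinctionError(
            f"population went extinct at generation {pop.generation + 1}"
        ) from exc
    return Population(h1=h1[0], h2=h2[0], generation=pop.generation + 1, arch=pop.arch)


def run_replicates(
    arch: Architecture,
    design: ExperimentDesign,
    model: FitnessModel | None,
    n_lines: int,
    seed,
) -> pd.DataFrame:
    """True (pre-observation) frequency trajectories for independent lines.

    Each line is initialized with a fresh HWE draw and evolved to the final
    generation; frequencies are recorded at the design's sampled generations.
    """
    rng = np.random.default_rng(seed)
    gens = list(design.sampled_generations)
    try:
        freqs, _ = simulate_batch(arch, model, design.Ne, n_lines, gens, rng)
    except ExtinctionError as exc:
        raise ExtinctionError(
            f"line T{(exc.population_index or 0) + 1} went extinct",
            line=f"T{(exc.population_index or 0) + 1}",
        ) from exc
    rows = []
    for i in range(n_lines):
        for j, g in enumerate(gens):
            rows.append(
                pd.DataFrame(
                    {
                        "line": f"T{i + 1}",
                        "treatment_flag": 1,
                        "generation": g,
                        "locus_id": arch.locus_ids,
                        "block_id": arch.block_ids,
                        "freq": freqs[i, j],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# neutral quantiles
# ---------------------------------------------------------------------------


@dataclass
class NeutralQuantiles:
    """Per (starting frequency, generation) thresholds of neutral frequency
    increase at quantile q, from frequency-level neutral WF simulation."""

    p0: np.ndarray  # (K,)
    generations: np.ndarray  # (T,)
    thresholds: np.ndarray  # (K, T)
    n_iterations: int
    Ne: int
    q: float

    def threshold(self, p0: float, generation: int) -> float:
        k = int(np.argmin(np.abs(self.p0 - p0)))
        if not np.isclose(self.p0[k], p0, atol=5e-3):
            raise KeyError(f"no thresholds for starting frequency {p0}")
        tsel = np.nonzero(self.generations == generation)[0]
        if tsel.size == 0:
            raise KeyError(f"no thresholds for generation {generation}")
        return float(self.thresholds[k, tsel[0]])

    def to_frame(self) -> pd.DataFrame:
        K, T = self.thresholds.shape
        return pd.DataFrame(
            {
                "p0": np.repeat(self.p0, T),
                "generation": np.tile(self.generations, K),
                "q": self.q,
                "threshold": self.thresholds.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_iterations: int = 0, Ne: int = 0) -> "NeutralQuantiles":
        df = pd.read_csv(path, sep="\t")
        p0 = np.array(sorted(df["p0"].unique()))
        gens = np.array(sorted(df["generation"].unique()))
        thr = np.empty((p0.size, gens.size))
        piv = df.pivot_table(index="p0", columns="generation", values="threshold")
        thr[:] = piv.loc[p0, gens].to_numpy()
        return cls(
            p0=p0,
            generations=gens,
            thresholds=thr,
            n_iterations=n_iterations,
            Ne=Ne,
            q=float(df["q"].iloc[0]),
        )


def neutral_quantiles(
    p0_values,
    Ne: int,
    generations: Sequence[int],
    n_iter: int = 10_000,
    q: float = 0.999,
    seed=0,
    pool_n: int | None = None,
    coverage_sampler: Callable | None = None,
) -> NeutralQuantiles:
    """Quantiles of neutral frequency increase (p_t - p0) per starting
    frequency and generation, over ``n_iter`` neutral WF iterations.

    With ``pool_n``/``coverage_sampler`` set, the Pool-seq observation layer
    (pool then read sampling) is applied before taking quantiles; the default
    (None) takes quantiles of the true frequency process.
    """
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000")
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p0 = np.atleast_1d(np.asarray(p0_values, dtype=float))
    gens = np.array(sorted(set(int(g) for g in generations)))
    if gens[0] < 1:
        raise ValueError("threshold generations must be >= 1")
    K = p0.size
    p = np.broadcast_to(p0, (n_iter, K)).copy()
    thr = np.empty((K, gens.size))
    j = 0
    for t in range(1, int(gens[-1]) + 1):
        p = rng.binomial(2 * Ne, p) / (2.0 * Ne)
        if t == gens[j]:
            obs = p
            if pool_n is not None:
                obs = rng.binomial(2 * pool_n, obs) / (2.0 * pool_n)
            if coverage_sampler is not None:
                cov = coverage_sampler(obs.shape, rng)
                obs = rng.binomial(cov, obs) / cov
            thr[:, j] = np.quantile(obs - p0, q, axis=0)
            j += 1
            if j == gens.size:
                break
    return NeutralQuantiles(
        p0=p0, generations=gens, thresholds=thr, n_iterations=n_iter, Ne=Ne, q=q
    )
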