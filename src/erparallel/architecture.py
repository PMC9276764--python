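"""Genetic architectures and experiment designs for E&R simulations.

An :class:`Architecture` is the set of selected loci segregating in the
founding population: each locus carries the frequency of the rising
(beneficial) allele, its selection coefficient, and a genomic position used
when physical linkage is simulated.  Architectures can be generated from
distribution specifications calibrated to the study system (a copepod
salinity-selection experiment: 121 haplotype-block alleles, mean rising-allele
frequency ~0.29, mean selection coefficient ~0.133) or loaded from TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ConfigurationError(ValueError):
    """Invalid configuration (distribution spec, design, or model parameters)."""


@dataclass(frozen=True)
class Locus:
    """One selected locus, polarized so the rising allele is beneficial.

    ``s`` is the per-generation selection coefficient of the rising allele
    (genotype fitnesses 1, 1 + s/2, 1 + s under the multiplicative model);
    ``p0`` its frequency in the founding population.
    """

    locus_id: str
    block_id: str
    scaffold: str
    position_bp: int
    s: float
    p0: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 1.0):
            raise ConfigurationError(f"p0 must be in (0, 1), got {self.p0}")
        if self.s < 0.0:
            raise ConfigurationError(f"s must be >= 0, got {self.s}")
        if self.position_bp < 0:
            raise ConfigurationError("position_bp must be >= 0")


@dataclass(frozen=True)
class Architecture:
    """Ordered collection of selected loci plus linkage configuration."""

    loci: tuple[Locus, ...]
    linkage_mode: str = "unlinked"  # "unlinked" | "linked"
    recomb_rate_cM_per_Mb: float = 1.6
    level: str = "block"  # "block" | "snp"

    def __post_init__(self) -> None:
        if self.linkage_mode not in ("unlinked", "linked"):
            raise ConfigurationError(f"unknown linkage_mode {self.linkage_mode!r}")
        if self.level not in ("block", "snp"):
            raise ConfigurationError(f"unknown level {self.level!r}")
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("locus_id values must be unique")
        if self.level == "block":
            blocks = [loc.block_id for loc in self.loci]
            if len(set(blocks)) != len(blocks):
                raise ConfigurationError(
                    "block-level architectures require one locus per block"
                )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def s(self) -> np.ndarray:
        return np.array([loc.s for loc in self.loci], dtype=float)

    @property
    def p0(self) -> np.ndarray:
        return np.array([loc.p0 for loc in self.loci], dtype=float)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    @property
    def block_ids(self) -> list[str]:
        return [loc.block_id for loc in self.loci]

    def crossover_probs(self) -> np.ndarray:
        """Per-adjacent-locus crossover probabilities via the Haldane map.

        Entry j is the probability of a crossover between loci j-1 and j in a
        gamete; entry 0 is 0.5 (the starting haplotype is random).  Loci on
        different scaffolds assort independently (r = 0.5).
        """
        r = np.full(self.n_loci, 0.5)
        for j in range(1, self.n_loci):
            a, b = self.loci[j - 1], self.loci[j]
            if a.scaffold == b.scaffold:
                d_bp = abs(b.position_bp - a.position_bp)
                morgans = d_bp / 1e6 * self.recomb_rate_cM_per_Mb / 100.0
                r[j] = 0.5 * (1.0 - np.exp(-2.0 * morgans))
        return r

    def with_p0(self, p0) -> "Architecture":
        """Return a copy with starting frequencies replaced (scalar or array)."""
        p0 = np.broadcast_to(np.asarray(p0, dtype=float), (self.n_loci,))
        loci = tuple(replace(loc, p0=float(p)) for loc, p in zip(self.loci, p0))
        return replace(self, loci=loci)

    def with_linkage(self, linkage_mode: str) -> "Architecture":
        return replace(self, linkage_mode=linkage_mode)

    def subsample(self, n_loci: int, seed: int) -> "Architecture":
        """Random subset of loci (order preserved), as used when the number of
        contributing loci is varied."""
        if not (1 <= n_loci <= self.n_loci):
            raise ConfigurationError("n_loci out of range for subsampling")
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(self.n_loci, size=n_loci, replace=False))
        return replace(self, loci=tuple(self.loci[i] for i in keep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "block_id": self.block_ids,
                "scaffold": [loc.scaffold for loc in self.loci],
                "position_bp": [loc.position_bp for loc in self.loci],
                "s": self.s,
                "p0": self.p0,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "Architecture":
        loci = tuple(
            Locus(
                locus_id=str(row.locus_id),
                block_id=str(row.block_id),
                scaffold=str(row.scaffold),
                position_bp=int(row.position_bp),
                s=float(row.s),
                p0=float(row.p0),
            )
            for row in df.itertuples()
        )
        return cls(loci=loci, **kwargs)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "Architecture":
        return cls.from_frame(pd.read_csv(path, sep="\t"), **kwargs)


@dataclass(frozen=True)
class ExperimentDesign:
    """Replication and observation design of the selection experiment.

    Defaults mirror the study: 10 treatment lines (2 extinct by the final
    generation), 4 control lines, sampling at generations 0/6/10, pools of
    100 individuals in simulations, read coverage in [10, 200], Ne = 1750.
    """

    n_treatment_lines: int = 10
    n_control_lines: int = 4
    n_extinct_at_final: int = 2
    sampled_generations: tuple[int, ...] = (0, 6, 10)
    pool_n_individuals: int = 100
    coverage_min: int = 10
    coverage_max: int = 200
    Ne: int = 1750
    final_generation: int = 10

    def __post_init__(self) -> None:
        gens = tuple(self.sampled_generations)
        object.__setattr__(self, "sampled_generations", gens)
        if list(gens) != sorted(gens) or gens[0] != 0:
            raise ConfigurationError(
                "sampled_generations must be ascending and start at 0"
            )
        if not (0 <= self.n_extinct_at_final < self.n_treatment_lines):
            raise ConfigurationError(
                "0 <= n_extinct_at_final < n_treatment_lines required"
            )
        if self.coverage_min < 1 or self.coverage_max < self.coverage_min:
            raise ConfigurationError("invalid coverage bounds")
        if self.pool_n_individuals < 1 or self.Ne < 2:
            raise ConfigurationError("invalid pool size or Ne")
        if self.final_generation < gens[-1]:
            raise ConfigurationError("final_generation before last sampled generation")


# ---------------------------------------------------------------------------
# Distribution specs
#
# A spec is a tuple: ("point", v) | ("uniform", lo, hi) | ("beta", a, b)
# | ("beta_ms", mean, sd) | ("gamma", shape, scale) | ("gamma_ms", mean, shape)
# ---------------------------------------------------------------------------

# Defaults calibrated once to the printed summaries of the study architecture:
# rising-allele frequencies with mean ~0.29 ranging ~0.10-0.47 (sd ~0.09),
# selection coefficients with mean 0.133 whose maximum over 121 draws ~0.372.
DEFAULT_FREQ_DIST = ("beta_ms", 0.29, 0.09)
DEFAULT_S_DIST = ("gamma_ms", 0.133, 4.0)
_SNPS_PER_BLOCK = 41  # ~4977 SNPs on 121 blocks


def _frozen_dist(spec):
    if not isinstance(spec, (tuple, list)) or not spec:
        raise ConfigurationError(f"invalid distribution spec: {spec!r}")
    kind, *params = spec
    try:
        if kind == "point":
            (v,) = params
            return ("point", float(v))
        if kind == "uniform":
            lo, hi = map(float, params)
            if hi < lo:
                raise ValueError
            return ("dist", stats.uniform(lo, hi - lo))
        if kind == "beta":
            a, b = map(float, params)
            if a <= 0 or b <= 0:
                raise ValueError
            return ("dist", stats.beta(a, b))
        if kind == "beta_ms":
            m, sd = map(float, params)
            if not (0 < m < 1) or sd <= 0 or sd * sd >= m * (1 - m):
                raise ValueError
            nu = m * (1 - m) / (sd * sd) - 1.0
            return ("dist", stats.beta(m * nu, (1 - m) * nu))
        if kind == "gamma":
            shape, scale = map(float, params)
            if shape <= 0 or scale <= 0:
                raise ValueError
            return ("dist", stats.gamma(shape, scale=scale))
        if kind == "gamma_ms":
            m, shape = map(float, params)
            if m <= 0 or shape <= 0:
                raise ValueError
            return ("dist", stats.gamma(shape, scale=m / shape))
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(f"invalid distribution parameters: {spec!r}") from exc
    raise ConfigurationError(f"unknown distribution kind: {kind!r}")


def _draw(spec, n: int, rng: np.random.Generator, bounds=None) -> np.ndarray:
    kind, obj = _frozen_dist(spec)
    if kind == "point":
        return np.full(n, obj)
    out = obj.rvs(size=n, random_state=rng)
    if bounds is not None:
        lo, hi = bounds
        # rejection sampling to stay within the admissible interval
        for _ in range(1000):
            bad = (out <= lo) | (out >= hi)
            if not bad.any():
                return out
            out[bad] = obj.rvs(size=int(bad.sum()), random_state=rng)
        raise ConfigurationError(
            f"distribution {spec!r} incompatible with bounds {bounds}"
        )
    return out


def gen_architecture(
    n_loci: int,
    freq_dist=DEFAULT_FREQ_DIST,
    s_dist=DEFAULT_S_DIST,
    level: str = "block",
    seed: int = 0,
    linkage_mode: str = "unlinked",
    recomb_rate_cM_per_Mb: float = 1.6,
    n_scaffolds: int = 4,
    genome_size_bp: int = 518_000_000,
) -> Architecture:
    """Generate a synthetic architecture of selected alleles.

    At block level each locus is one haplotype-block allele; blocks are placed
    >= 1 Mb apart on ``n_scaffolds`` scaffolds.  At snp level, ``n_loci`` SNPs
    are grouped ~41 per block and share their block's position neighbourhood.
    Deterministic given ``seed``.
    """
    if n_loci < 1:
        raise ConfigurationError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    p0 = _draw(freq_dist, n_loci, rng, bounds=(0.05, 0.95))
    s = _draw(s_dist, n_loci, rng)
    s = np.clip(s, 0.0, None)

    loci: list[Locus] = []
    if level == "block":
        n_blocks = n_loci
        block_of = np.arange(n_loci)
    else:
        n_blocks = max(1, int(np.ceil(n_loci / _SNPS_PER_BLOCK)))
        block_of = np.sort(rng.integers(0, n_blocks, size=n_loci))
        # ensure every block is used at least once
        block_of[:n_blocks] = np.arange(n_blocks)
        block_of = np.sort(block_of)
    # block positions: blocks spread roughly evenly across the genome
    # (round-robin over scaffolds, gaps ~ U(0.5, 1.5) x the mean spacing
    # genome_size / n_blocks, floored at 1 Mb)
    scaf_of_block = np.arange(n_blocks) % n_scaffolds
    pos_of_block = np.zeros(n_blocks, dtype=np.int64)
    cursor = np.zeros(n_scaffolds, dtype=np.int64)
    mean_gap = max(2_000_000, genome_size_bp // n_blocks)
    gaps = rng.integers(max(1_000_000, mean_gap // 2), mean_gap * 3 // 2,
                        size=n_blocks)
    for b in range(n_blocks):
        sc = scaf_of_block[b]
        cursor[sc] += gaps[b]
        pos_of_block[b] = cursor[sc]
    within = np.zeros(n_loci, dtype=np.int64)
    if level == "snp":
        # SNPs spread within ~1.9 Mb blocks
        offsets = rng.integers(0, 1_890_000, size=n_loci)
        order = np.argsort(block_of * 10_000_000 + offsets, kind="stable")
        within = offsets
    for i in range(n_loci):
        b = int(block_of[i])
        loci.append(
            Locus(
                locus_id=f"L{i:05d}",
                block_id=f"B{b:04d}",
                scaffold=f"scaf{scaf_of_block[b] + 1}",
                position_bp=int(pos_of_block[b] + within[i]),
                s=float(s[i]),
                p0=float(p0[i]),
            )
        )
    # keep loci sorted by genomic coordinate within scaffolds for linkage
    loci.sort(key=lambda loc: (loc.scaffold, loc.position_bp, loc.locus_id))
    return Architecture(
        loci=tuple(loci),
        linkage_mode=linkage_mode,
        recomb_rate_cM_per_Mb=recomb_rate_cM_per_Mb,
        level=level,
    )
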