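"""Pool-seq observation layer and trajectory-table I/O.

True population states are observed in two stages, the common Pool-seq
sampling model: (1) a pool of ``pool_n`` individuals is drawn without
replacement from the population (hypergeometric at the individual level),
(2) read counts are drawn binomially from the pool allele frequency at a
per-locus sequencing coverage.  The observation adds variance but no bias.

``n_eff`` is the standard Pool-seq effective number of allele copies
combining pool size and read depth; it is used as a regression weight by the
inference module.

Trajectory tables are tidy DataFrames with columns
``line, treatment_flag, generation, locus_id, block_id, alt_count, coverage,
pool_n, freq`` and can be written/read as TSV or popoolation2-style sync
files (biallelic: rising-allele count vs the rest).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

TRAJ_COLUMNS = [
    "line",
    "treatment_flag",
    "generation",
    "locus_id",
    "block_id",
    "alt_count",
    "coverage",
    "pool_n",
    "freq",
]


def n_eff(pool_n, coverage):
    """Effective number of allele copies: harmonic combination of 2*pool_n
    chromosomes and read coverage; bounded by min(2*pool_n, coverage)."""
    pool_n = np.asarray(pool_n, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    if np.any(pool_n < 1) or np.any(coverage < 1):
        raise ValueError("pool_n and coverage must be >= 1")
    out = (2.0 * pool_n * coverage) / (2.0 * pool_n + coverage)
    return float(out) if out.ndim == 0 else out


def uniform_coverage(lo: int = 10, hi: int = 200) -> Callable:
    """Coverage sampler: integer-uniform on [lo, hi] (inclusive)."""
    if lo < 1 or hi < lo:
        raise ValueError("invalid coverage bounds")

    def sampler(shape, rng: np.random.Generator):
        return rng.integers(lo, hi + 1, size=shape)

    return sampler


def sample_reads(
    pool_freq: np.ndarray,
    coverage_sampler: Callable,
    rng: np.random.Generator,
):
    """Binomial read sampling at sampled coverage; returns (alt_count, coverage)."""
    pool_freq = np.asarray(pool_freq, dtype=float)
    cov = np.asarray(coverage_sampler(pool_freq.shape, rng))
    alt = rng.binomial(cov, pool_freq)
    return alt, cov


def observe(pop, pool_n: int, coverage_sampler: Callable, seed):
    """Observe a Population through the two-stage Pool-seq model.

    Returns per-locus (alt_count, coverage).
    """
    from .wf import _pool_counts

    if pool_n > pop.N:
        raise ValueError("pool_n exceeds population size")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    G = (pop.h1 + pop.h2)[None]
    pooled = _pool_counts(G, pool_n, rng)[0]
    qpool = pooled / (2.0 * pool_n)
    return sample_reads(qpool, coverage_sampler, rng)


# ---------------------------------------------------------------------------
# trajectory table I/O
# ---------------------------------------------------------------------------


def write_trajectory_tsv(traj: pd.DataFrame, path) -> None:
    traj.to_csv(path, sep="\t", index=False, columns=[c for c in TRAJ_COLUMNS if c in traj])


def read_trajectory_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "freq" not in df and {"alt_count", "coverage"} <= set(df.columns):
        df["freq"] = df["alt_count"] / df["coverage"]
    return df


def write_sync(traj: pd.DataFrame, path) -> None:
    """Write a popoolation2-style sync file.

    One row per locus; one column per (line, generation) sample holding
    ``A:T:C:G:N:del`` counts with the rising allele written as T and the
    alternative as A.  Sample order is the sorted (line, generation) pairs;
    a header comment records it.
    """
    df = traj.copy()
    samples = sorted(df[["line", "generation"]].drop_duplicates().itertuples(index=False))
    loci = df[["locus_id", "block_id"]].drop_duplicates("locus_id")
    piv_alt = df.pivot_table(index="locus_id", columns=["line", "generation"], values="alt_count")
    piv_cov = df.pivot_table(index="locus_id", columns=["line", "generation"], values="coverage")
    with open(path, "w") as fh:
        fh.write("#chr\tpos\tref\t" + "\t".join(f"{l}.g{g}" for l, g in samples) + "\n")
        for i, row in enumerate(loci.itertuples(index=False)):
            lid = row.locus_id
            fields = [str(row.block_id), str(i + 1), "A"]
            for l, g in samples:
                alt = piv_alt.loc[lid, (l, g)]
                cov = piv_cov.loc[lid, (l, g)]
                if np.isnan(alt) or np.isnan(cov):
                    fields.append("0:0:0:0:0:0")
                else:
                    fields.append(f"{int(cov - alt)}:{int(alt)}:0:0:0:0")
            fh.write("\t".join(fields) + "\n")


def read_sync(path) -> pd.DataFrame:
    """Read a sync file written by :func:`write_sync` (or any biallelic sync
    with the rising allele as T) back into a trajectory table."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header[0].startswith("#"):
            raise ValueError("sync file lacks the sample-order header")
        samples = [h.rsplit(".g", 1) for h in header[3:]]
        rows = []
        for li, line_txt in enumerate(fh):
            fields = line_txt.rstrip("\n").split("\t")
            block, _pos = fields[0], fields[1]
            for (line, gen), cell in zip(samples, fields[3:]):
                counts = [int(c) for c in cell.split(":")]
                cov = sum(counts)
                if cov == 0:
                    continue
                rows.append(
                    {
                        "line": line,
                        "generation": int(gen),
                        "locus_id": f"L{li:05d}",
                        "block_id": block,
                        "alt_count": counts[1],
                        "coverage": cov,
                        "freq": counts[1] / cov,
                    }
                )
    return pd.DataFrame(rows)
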