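"""Detection of selected alleles and estimation of selection coefficients.

Four complementary procedures, mirroring the analysis of the experiment:

* ``call_selected`` -- per line and timepoint, an allele is called selected
  when its observed frequency increase exceeds the chosen quantile (default
  99.9%) of neutral WF simulations for its starting frequency.
* ``cmh_drift_test`` / ``chisq_line_test`` -- Cochran-Mantel-Haenszel-type
  tests on 2x2 count tables per line and timepoint, with each stratum's
  variance inflated for genetic drift (p(1-p)[1-(1-1/(2Ne))^t]) and two-stage
  Pool-seq sampling, including within-line covariance across timepoints.
* ``lmm_treatment_test`` -- likelihood-ratio test contrasting treatment and
  control frequency trajectories on the arcsine-square-root scale with
  N_eff weights and a line random intercept.
* ``estimate_s`` -- slope of the logit-frequency regression on generation,
  per locus, either pooled over per-line weighted fits or as a mixed model
  with a line random intercept; optional inversion to the diploid selection
  coefficient of the 1, 1+hs, 1+s fitness parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmm import fit_weighted_lmm
from .observe import n_eff
from .wf import NeutralQuantiles


# ---------------------------------------------------------------------------
# neutral-quantile calling
# ---------------------------------------------------------------------------


@dataclass
class SelectionCalls:
    """Boolean call per (line, locus, generation) plus thresholds used."""

    calls: pd.DataFrame  # columns: line, locus_id, generation, call
    thresholds: NeutralQuantiles
    q: float

    def selected_set(self, line: str, generation: int) -> set:
        sub = self.calls[
            (self.calls["line"] == line)
            & (self.calls["generation"] == generation)
            & self.calls["call"]
        ]
        return set(sub["locus_id"])

    def lines(self, generation: int) -> list[str]:
        sub = self.calls[self.calls["generation"] == generation]
        return sorted(sub["line"].unique())

    def per_line_counts(self, generation: int) -> pd.Series:
        sub = self.calls[self.calls["generation"] == generation]
        return sub.groupby("line")["call"].sum()


def call_selected(
    traj: pd.DataFrame,
    nq: NeutralQuantiles,
    p0_ref=None,
    treatment_only: bool = True,
    threshold_generation: int | str = "final",
) -> SelectionCalls:
    """Call selected alleles per line and timepoint.

    The observed shift is ``freq(t) - p0_hat`` with ``p0_hat`` the mean of
    the generation-0 samples per locus; the threshold is looked up at the
    reference starting frequency ``p0_ref`` (defaults to ``p0_hat``).
    Mirroring the experiment's calling rule, the final-generation neutral
    quantile is applied at every timepoint by default; pass
    ``threshold_generation="per_generation"`` to use each timepoint's own
    quantile.  One-sided: only frequency increases are called.
    """
    base = traj[traj["generation"] == 0]
    if base.empty:
        raise ValueError("trajectory table has no generation-0 samples")
    p0_hat = base.groupby("locus_id")["freq"].mean()
    sub = traj[traj["generation"] > 0]
    if treatment_only and "treatment_flag" in sub:
        sub = sub[sub["treatment_flag"] == 1]
    loci = sub["locus_id"].drop_duplicates().to_numpy()
    missing = set(loci) - set(p0_hat.index)
    if missing:
        raise KeyError(f"no generation-0 sample for loci {sorted(missing)[:3]}...")
    if p0_ref is None:
        ref = p0_hat
    else:
        ref = pd.Series(np.asarray(p0_ref, dtype=float), index=loci)
    # nearest-neighbour threshold lookup per (locus, generation)
    gen_col = {int(g): j for j, g in enumerate(nq.generations)}
    k_of = np.abs(ref.to_numpy()[:, None] - nq.p0[None, :]).argmin(axis=1)
    k_map = pd.Series(k_of, index=ref.index)
    rows = sub[["line", "locus_id", "generation", "freq"]].copy()
    if threshold_generation == "per_generation":
        gen_for_thr = rows["generation"]
    else:
        g_fixed = (
            int(nq.generations.max())
            if threshold_generation == "final"
            else int(threshold_generation)
        )
        gen_for_thr = pd.Series(g_fixed, index=rows.index)
    jcol_f = gen_for_thr.map(gen_col)
    if jcol_f.isna().any():
        missing_g = sorted(gen_for_thr[jcol_f.isna()].unique())
        raise KeyError(f"missing neutral thresholds for generations {missing_g}")
    jcol = jcol_f.to_numpy(dtype=int)
    thr = nq.thresholds[k_map.loc[rows["locus_id"]].to_numpy(), jcol]
    rows["call"] = (
        rows["freq"].to_numpy() - p0_hat.loc[rows["locus_id"]].to_numpy()
    ) > thr
    return SelectionCalls(
        calls=rows[["line", "locus_id", "generation", "call"]].reset_index(drop=True),
        thresholds=nq,
        q=nq.q,
    )


# ---------------------------------------------------------------------------
# selection-coefficient estimation
# ---------------------------------------------------------------------------


def slope_to_s(slope, h: float = 0.5):
    """Invert the logit-slope -> selection-coefficient map for genotype
    fitnesses 1, 1+hs, 1+s: slope = log((1+s)/(1+hs)), so
    s = (e^b - 1)/(1 - h e^b)."""
    eb = np.exp(np.asarray(slope, dtype=float))
    denom = 1.0 - h * eb
    out = np.where(denom > 0, (eb - 1.0) / np.where(denom > 0, denom, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def _clamped_logit(p, neff):
    eps = 1.0 / (2.0 * neff + 2.0)
    pc = np.clip(p, eps, 1.0 - eps)
    return np.log(pc / (1.0 - pc))


def estimate_s(
    traj: pd.DataFrame,
    use_random_line_effect: bool = True,
    dominance: float | None = None,
    treatment_only: bool = True,
) -> pd.DataFrame:
    """Per-locus selection-coefficient estimates from logit-frequency slopes.

    With ``use_random_line_effect`` the slope comes from a weighted mixed
    model (line random intercept, weights N_eff); otherwise per-line weighted
    least-squares slopes are averaged across lines.  ``dominance`` (e.g. 0.5)
    converts the raw slope to the s of the 1, 1+hs, 1+s parameterization;
    the default returns the slope itself.

    Requires per-line generation-0 rows (see ``synth.attach_baseline``).
    """
    df = traj.copy()
    if treatment_only and "treatment_flag" in df:
        df = df[(df["treatment_flag"] == 1) | df["line"].str.startswith("S")]
    lines_with_t = df[df["generation"] > 0]["line"].unique()
    if not set(df[df["generation"] == 0]["line"]) >= set(lines_with_t):
        from .synth import attach_baseline

        df = attach_baseline(df)
        if treatment_only and "treatment_flag" in df:
            df = df[df["treatment_flag"] == 1]
    df = df[df["line"].isin(lines_with_t)]
    if df.groupby("line")["generation"].nunique().max() < 2:
        raise ValueError("need >= 2 timepoints per line")
    df["neff"] = n_eff(df["pool_n"], df["coverage"])
    out = []
    for locus, sub in df.groupby("locus_id", sort=False):
        p = sub["freq"].to_numpy(dtype=float)
        if np.all((p == 0.0) | (p == 1.0)):
            out.append((locus, np.nan, np.nan))
            continue
        y = _clamped_logit(p, sub["neff"].to_numpy())
        t = sub["generation"].to_numpy(dtype=float)
        w = sub["neff"].to_numpy(dtype=float)
        if use_random_line_effect:
            X = np.column_stack([np.ones_like(t), t])
            fit = fit_weighted_lmm(y, X, sub["line"].to_numpy(), w)
            slope, se = fit.beta[1], np.sqrt(fit.cov_beta[1, 1])
        else:
            slopes = []
            for _, ls in sub.groupby("line"):
                tt = ls["generation"].to_numpy(dtype=float)
                if np.unique(tt).size < 2:
                    continue
                yy = _clamped_logit(ls["freq"].to_numpy(), ls["neff"].to_numpy())
                ww = ls["neff"].to_numpy(dtype=float)
                Xl = np.column_stack([np.ones_like(tt), tt])
                XtW = Xl.T * ww
                b = np.linalg.solve(XtW @ Xl, XtW @ yy)
                slopes.append(b[1])
            slopes = np.array(slopes)
            slope = slopes.mean()
            se = (
                slopes.std(ddof=1) / np.sqrt(slopes.size)
                if slopes.size > 1
                else np.nan
            )
        out.append((locus, slope, se))
    res = pd.DataFrame(out, columns=["locus_id", "s_hat", "se"]).set_index("locus_id")
    if dominance is not None:
        res["s_hat"] = slope_to_s(res["s_hat"].to_numpy(), h=dominance)
        res["se"] = np.nan  # delta-method SE not propagated through inversion
    return res


# ---------------------------------------------------------------------------
# drift-adjusted CMH / chi-square tests
# ---------------------------------------------------------------------------


def _cmh_components(alt, cov, generations, Ne, pool_n):
    """Per-locus numerator and variance of the drift/Pool-seq-adjusted CMH
    statistic. alt, cov: (n_lines, T, L) with generations[0] == 0."""
    alt = np.asarray(alt, dtype=float)
    cov = np.asarray(cov, dtype=float)
    n_lines, T, L = alt.shape
    gens = np.asarray(generations, dtype=float)
    if gens[0] != 0 or T < 2:
        raise ValueError("need generation-0 baseline plus >= 1 later timepoint")
    if not np.isfinite(Ne) or Ne <= 0:
        if not (Ne == np.inf):
            raise ValueError("Ne must be positive (np.inf disables drift)")
    drift = 1.0 - (1.0 - 1.0 / (2.0 * Ne)) ** gens if np.isfinite(Ne) else np.zeros(T)
    pool_extra = 0.0
    if pool_n is not None:
        pool_extra = 1.0 / (2.0 * pool_n)  # per-sample pool-stage extra variance
    U = np.zeros(L)
    V = np.zeros(L)
    wk = np.empty((n_lines, T, L))
    pbar = np.empty((n_lines, T, L))
    for j in range(1, T):
        a = alt[:, j]
        c0, ct = cov[:, 0], cov[:, j]
        x0 = alt[:, 0]
        Tk = c0 + ct
        m1 = x0 + a
        m2 = Tk - m1
        E = ct * m1 / Tk
        with np.errstate(invalid="ignore", divide="ignore"):
            Vh = c0 * ct * m1 * m2 / (Tk**2 * np.maximum(Tk - 1.0, 1.0))
        w = c0 * ct / Tk
        p = m1 / Tk
        pq = p * (1.0 - p)
        extra = drift[j] + (
            pool_extra * (2.0 - 1.0 / c0 - 1.0 / ct) if pool_n is not None else 0.0
        )
        U += (a - E).sum(axis=0)
        V += (Vh + w**2 * pq * extra).sum(axis=0)
        wk[:, j] = w
        pbar[:, j] = pq
    # within-line covariance across timepoints: shared drift up to the earlier
    # timepoint, shared pool-stage baseline noise, shared baseline reads
    for j in range(1, T):
        for j2 in range(j + 1, T):
            pq = 0.5 * (pbar[:, j] + pbar[:, j2])
            c0 = cov[:, 0]
            shared = drift[j] + (
                pool_extra * (1.0 - 1.0 / c0) if pool_n is not None else 0.0
            )
            if np.isfinite(Ne) or pool_n is not None:
                shared = shared + 1.0 / c0  # baseline read sampling, shared
            V += 2.0 * (wk[:, j] * wk[:, j2] * pq * shared).sum(axis=0)
    return U, V


def _test_frame(stat, p, loci, name):
    q = fdr_adjust(p)
    return pd.DataFrame(
        {"locus_id": loci, "statistic": stat, "p_value": p, "q_value": q,
         "test_name": name}
    ).set_index("locus_id")


def cmh_drift_test(
    alt,
    cov,
    generations,
    Ne,
    pool_n: int | None = None,
    locus_ids=None,
) -> pd.DataFrame:
    """Drift/Pool-seq-adjusted CMH test across replicate lines and timepoints.

    ``alt``/``cov`` have shape (n_lines, T, L); ``generations[0]`` must be 0
    (the baseline).  With ``Ne = np.inf`` and ``pool_n = None`` the statistic
    is exactly the classical CMH statistic on the same 2x2 tables.
    """
    alt = np.asarray(alt, dtype=float)
    if alt.shape[0] < 2:
        raise ValueError("cmh_drift_test needs >= 2 replicate lines")
    U, V = _cmh_components(alt, cov, generations, Ne, pool_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(V > 0, U**2 / np.where(V > 0, V, 1.0), 0.0)
    p = stats.chi2.sf(stat, df=1)
    loci = locus_ids if locus_ids is not None else np.arange(alt.shape[2])
    return _test_frame(stat, p, loci, "cmh_drift")


def chisq_line_test(
    alt, cov, generations, Ne, pool_n: int | None = None, locus_ids=None
) -> pd.DataFrame:
    """Single-line analogue of :func:`cmh_drift_test` (line-specific test)."""
    alt = np.asarray(alt, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if alt.ndim == 2:
        alt, cov = alt[None], cov[None]
    if alt.shape[0] != 1:
        raise ValueError("chisq_line_test takes a single line")
    U, V = _cmh_components(alt, cov, generations, Ne, pool_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(V > 0, U**2 / np.where(V > 0, V, 1.0), 0.0)
    p = stats.chi2.sf(stat, df=1)
    loci = locus_ids if locus_ids is not None else np.arange(alt.shape[2])
    return _test_frame(stat, p, loci, "chisq_line")


def traj_to_count_arrays(traj: pd.DataFrame, treatment_flag: int = 1):
    """Pivot a trajectory table (with per-line generation-0 rows) into
    (alt, cov, generations, lines, loci) arrays for the count-based tests.
    Lines lacking any sampled generation are dropped (e.g. extinct lines when
    the final generation is required)."""
    df = traj[traj["treatment_flag"] == treatment_flag] if "treatment_flag" in traj else traj
    gens = sorted(df["generation"].unique())
    piv_a = df.pivot_table(index="line", columns=["generation", "locus_id"],
                           values="alt_count")
    complete = piv_a.dropna().index
    piv_a = piv_a.loc[complete]
    piv_c = df.pivot_table(index="line", columns=["generation", "locus_id"],
                           values="coverage").loc[complete]
    loci = df["locus_id"].drop_duplicates().to_numpy()
    T, L, n = len(gens), len(loci), len(complete)
    alt = piv_a.to_numpy().reshape(n, T, L)
    cov = piv_c.to_numpy().reshape(n, T, L)
    return alt, cov, np.array(gens), list(complete), loci


# ---------------------------------------------------------------------------
# LMM treatment-vs-control test
# ---------------------------------------------------------------------------


def lmm_treatment_test(traj: pd.DataFrame) -> pd.DataFrame:
    """Likelihood-ratio test for treatment-dependent frequency trajectories.

    Response: arcsin(sqrt(p_t)) - arcsin(sqrt(p_0)) per line and post-baseline
    generation, weights proportional to N_eff, line as a random intercept.
    Null model: ~ generation; alternative adds treatment and its interaction
    with generation.  The LRT statistic is referred to chi-square with df
    equal to the number of added fixed effects (2 for two timepoints).
    """
    from .synth import attach_baseline

    df = traj.copy()
    lines_with_t = df[df["generation"] > 0]["line"].unique()
    if not set(df[df["generation"] == 0]["line"]) >= set(lines_with_t):
        df = attach_baseline(df)
    df = df[df["line"].isin(lines_with_t)]
    post = df[df["generation"] > 0].copy()
    n_treat = post[post["treatment_flag"] == 1]["line"].nunique()
    n_ctrl = post[post["treatment_flag"] == 0]["line"].nunique()
    if n_treat < 2 or n_ctrl < 2:
        raise ValueError("need >= 2 treatment and >= 2 control lines")
    gens = sorted(post["generation"].unique())
    if len(gens) < 2:
        raise ValueError("need >= 2 post-baseline timepoints")
    base = df[df["generation"] == 0].set_index(["line", "locus_id"])["freq"]
    post["y"] = np.arcsin(np.sqrt(post["freq"].to_numpy())) - np.arcsin(
        np.sqrt(base.loc[list(zip(post["line"], post["locus_id"]))].to_numpy())
    )
    post["neff"] = n_eff(post["pool_n"], post["coverage"])
    gen_dummies = {g: (post["generation"] == g).to_numpy(dtype=float) for g in gens[1:]}
    treat = post["treatment_flag"].to_numpy(dtype=float)
    out = []
    for locus, sub in post.groupby("locus_id", sort=False):
        idx = sub.index
        y = sub["y"].to_numpy()
        w = sub["neff"].to_numpy()
        g = sub["line"].to_numpy()
        ones = np.ones(len(sub))
        gcols = [gen_dummies[gg][post.index.get_indexer(idx)] for gg in gens[1:]]
        tcol = treat[post.index.get_indexer(idx)]
        X0 = np.column_stack([ones, *gcols])
        X1 = np.column_stack(
            [ones, *gcols, tcol, *[gc * tcol for gc in gcols]]
        )
        if np.allclose(y, y[0]):
            out.append((locus, 0.0, 1.0))
            continue
        f0 = fit_weighted_lmm(y, X0, g, w)
        f1 = fit_weighted_lmm(y, X1, g, w)
        if not (np.isfinite(f0.loglik) and np.isfinite(f1.loglik)):
            out.append((locus, np.nan, np.nan))
            continue
        lrt = max(0.0, 2.0 * (f1.loglik - f0.loglik))
        dfree = X1.shape[1] - X0.shape[1]
        out.append((locus, lrt, stats.chi2.sf(lrt, df=dfree)))
    res = pd.DataFrame(out, columns=["locus_id", "statistic", "p_value"])
    res["q_value"] = fdr_adjust(res["p_value"].to_numpy())
    res["test_name"] = "lmm_treatment"
    return res.set_index("locus_id")


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in rank).

    NaNs are passed through unadjusted."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
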