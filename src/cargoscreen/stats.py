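"""Core screen statistics.

The analysis compares guide abundance between two FACS-sorted populations
(cargo-low vs cargo-high). It proceeds in four steps:

1. median-ratio normalization of the raw counts (DESeq-style size factors);
2. a one-sided per-sgRNA enrichment test: observed cargo-low abundance
   against a negative-binomial model fitted on the cargo-high (control)
   samples, variance mu + phi*mu^2;
3. gene-level aggregation of the sgRNA ranks with alpha-RRA: the gene score
   rho is the minimum over order-statistic binomial tail probabilities of
   the gene's guide ranks, restricted to guides individually significant at
   level alpha, with a permutation p-value from random rank sets;
4. duplicate-guide-set resolution (keep the higher-ranking set) and hit
   calling at an unadjusted p threshold (default 0.01).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from cargoscreen.io import CountMatrix, GuideLibrary

logger = logging.getLogger("cargoscreen")

DEFAULT_ALPHA = 0.05
DEFAULT_PERMUTATIONS = 10_000
DEFAULT_PRIOR_DISPERSION = 0.05

_MU_FLOOR = 1e-2  # keeps the NB tail defined for guides absent from control


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def median_ratio_normalize(cm: CountMatrix) -> CountMatrix:
    """Median-of-ratios size factors (DESeq convention).

    s_j = median_i c_ij / g_i over guides i whose counts are positive in
    every sample, with g_i the geometric mean of guide i across samples.
    Size factors are rescaled to geometric mean 1, so the result is
    invariant to a common depth rescaling. Falls back to total-count
    scaling (with a warning) when the median ratio is zero or undefined.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("normalization requires at least 2 samples")
    vals = counts.values
    all_pos = (vals > 0).all(axis=1)
    factors = np.ones(vals.shape[1])
    ok = True
    if all_pos.sum() == 0:
        ok = False
    else:
        log_g = np.log(vals[all_pos]).mean(axis=1, keepdims=True)
        ratios = vals[all_pos] / np.exp(log_g)
        factors = np.median(ratios, axis=0)
        if (factors <= 0).any() or not np.isfinite(factors).all():
            ok = False
    if not ok:
        logger.warning("median-ratio factors undefined; falling back to "
                       "total-count scaling")
        totals = vals.sum(axis=0).astype(float)
        factors = totals / totals.mean()
    factors = factors / np.exp(np.log(factors).mean())
    norm = counts / factors
    return CountMatrix(norm, cm.genes, cm.samples)


# ---------------------------------------------------------------------------
# per-sgRNA enrichment test
# ---------------------------------------------------------------------------

def fit_dispersion(control: pd.DataFrame) -> float:
    """Least-squares fit of phi in var = mu + phi*mu^2 across control
    samples (no intercept, regressing var - mu on mu^2), clamped at 0."""
    mu = control.mean(axis=1).to_numpy()
    var = control.var(axis=1, ddof=1).to_numpy()
    keep = mu > 0
    mu, var = mu[keep], var[keep]
    if len(mu) == 0:
        return 0.0
    phi = float(np.sum(mu**2 * (var - mu)) / np.sum(mu**4))
    return max(phi, 0.0)


def nb_tail(x: np.ndarray | float, mu: np.ndarray | float,
            phi: float) -> np.ndarray | float:
    """P(X >= x) for X ~ NB with mean mu and variance mu + phi*mu^2
    (Poisson when phi == 0)."""
    x = np.asarray(x, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    if phi == 0.0:
        return sps.poisson.sf(x - 1, mu)
    r = 1.0 / phi
    return sps.nbinom.sf(x - 1, r, r / (r + mu))


def sgrna_test(
    norm: CountMatrix,
    prior_dispersion: float = DEFAULT_PRIOR_DISPERSION,
    sum_replicates: bool = False,
) -> pd.DataFrame:
    """One-sided per-sgRNA enrichment test (cargo-low vs cargo-high).

    Replicates are grouped as a single comparison: the control mean is the
    mean normalized cargo-high count; the tested statistic is the rounded
    mean (or, optionally, sum-rescaled mean) of the cargo-low counts;
    p_i = P(X >= x_i) under NB(mu_i, phi) with phi fitted across control
    samples. Returns one row per guide with normalized ranks
    u_i = rank_i / M ascending in p (rank 1 = most cargo-low-enriched),
    ties broken by larger fold change then guide id.
    """
    norm.require_comparison()
    low_cols = norm.columns_for("tau_low")
    high_cols = norm.columns_for("tau_high")
    control = norm.counts[high_cols]
    treatment = norm.counts[low_cols]

    if len(high_cols) >= 2:
        phi = fit_dispersion(control)
    else:
        logger.warning("single control sample: dispersion falls back to "
                       "prior %.3g", prior_dispersion)
        phi = prior_dispersion

    mu_c = control.mean(axis=1)
    if sum_replicates:
        x = np.round(treatment.sum(axis=1) / len(low_cols))
    else:
        x = np.round(treatment.mean(axis=1))
    p = nb_tail(x.to_numpy(), mu_c.to_numpy(), phi)

    out = pd.DataFrame({
        "gene": norm.genes,
        "mean_control": mu_c,
        "mean_treatment": treatment.mean(axis=1),
        "p": p,
    }, index=norm.counts.index)
    out["fold"] = (out["mean_treatment"] + 0.5) / (out["mean_control"] + 0.5)
    # p ascending, fold descending, guide id as the final deterministic key
    order = (out.assign(_neg_fold=-out["fold"], _gid=out.index)
             .sort_values(["p", "_neg_fold", "_gid"], kind="mergesort"))
    M = len(order)
    rank = pd.Series(np.arange(1, M + 1), index=order.index)
    out["rank"] = rank
    out["u"] = rank / M
    out.attrs["dispersion"] = phi
    return out.sort_index()


# ---------------------------------------------------------------------------
# alpha-RRA
# ---------------------------------------------------------------------------

def rra_rho(u_sorted: Sequence[float], k_prime: int | None = None) -> float:
    """Robust-rank-aggregation gene score.

    Given a gene's k normalized guide ranks sorted ascending, with the first
    k' individually significant, rho = min over j = 1..k' of
    P(Bin(k, u_(j)) >= j). A single guide reduces to rho = u.
    """
    u = np.asarray(u_sorted, dtype=float)
    k = len(u)
    if k == 0:
        raise ValueError("no guide ranks supplied")
    if np.any(np.diff(u) < 0):
        raise ValueError("u_sorted must be ascending")
    if np.any((u <= 0) | (u > 1)):
        raise ValueError("ranks must lie in (0, 1]")
    kp = k if k_prime is None else int(k_prime)
    if not 1 <= kp <= k:
        raise ValueError("need 1 <= k_prime <= k")
    j = np.arange(1, kp + 1)
    tails = sps.binom.sf(j - 1, k, u[:kp])
    return float(tails.min())


def _rho_matrix(u: np.ndarray, k_prime: np.ndarray) -> np.ndarray:
    """Row-wise rho for U (n, k) with rows sorted ascending; rows where
    k_prime == 0 get rho = 1 (no individually significant guide)."""
    n, k = u.shape
    j = np.arange(1, k + 1)
    tails = sps.binom.sf(j - 1, k, u)
    mask = j[None, :] > k_prime[:, None]
    tails = np.where(mask, np.inf, tails)
    rho = tails.min(axis=1)
    rho[k_prime == 0] = 1.0
    return rho


def _null_rank_sets(k: int, M: int, B: int,
                    rng: np.random.Generator) -> np.ndarray:
    """B random sets of k distinct ranks out of M, as sorted u = idx/M."""
    if k >= M:
        raise ValueError("k must be < M")
    idx = rng.integers(1, M + 1, size=(B, k))
    if k > 1:
        # redraw rows with repeated ranks (without-replacement sampling)
        for _ in range(1000):
            idx.sort(axis=1)
            bad = (np.diff(idx, axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(1, M + 1, size=(int(bad.sum()), k))
        else:  # pragma: no cover
            raise RuntimeError("rank resampling failed to converge")
    return np.sort(idx, axis=1) / M


def rra_gene_pvalues(
    stats: pd.DataFrame,
    library: GuideLibrary,
    alpha: float = DEFAULT_ALPHA,
    B: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level alpha-RRA scores with permutation p-values.

    Per (gene, guide_set): k' counts guides with sgRNA p < alpha; rho comes
    from :func:`rra_rho` on the gene's sorted ranks. The null draws B random
    k-subsets of all M ranks (shared across genes with equal k), applies the
    same selection rule via the rank-space cutoff #{p < alpha}/M, and
    p = (1 + #{rho_null <= rho_obs}) / (B + 1). BH FDR across all guide
    sets.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if B < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    lib = library.table
    known = set(lib["gene_id"])
    stat_genes = set(stats["gene"])
    unknown = stat_genes - known
    if unknown:
        raise KeyError(f"gene(s) absent from library: {sorted(unknown)[:5]}")

    merged = stats.reset_index(names="guide_id").merge(
        lib[["guide_id", "gene_id", "guide_set"]], on="guide_id", how="inner")
    M = len(stats)
    t_sel = (stats["p"] < alpha).sum() / M  # selection cutoff in rank space

    groups = merged.groupby(["gene_id", "guide_set"], sort=True)
    rows = []
    by_k: dict[int, list[int]] = {}
    obs_u: list[np.ndarray] = []
    obs_kp: list[int] = []
    for (gene, gset), g in groups:
        u = np.sort(g["u"].to_numpy())
        kp = int((g["p"] < alpha).sum())
        rows.append((gene, gset, len(u), kp))
        by_k.setdefault(len(u), []).append(len(obs_u))
        obs_u.append(u)
        obs_kp.append(kp)

    rho = np.ones(len(rows))
    pperm = np.ones(len(rows))
    for k, members in by_k.items():
        U = np.vstack([obs_u[i] for i in members])
        kp = np.array([obs_kp[i] for i in members])
        rho_obs = _rho_matrix(U, kp)
        null_u = _null_rank_sets(k, M, B, rng)
        null_kp = (null_u <= t_sel).sum(axis=1)
        rho_null = np.sort(_rho_matrix(null_u, null_kp))
        hits = np.searchsorted(rho_null, rho_obs, side="right")
        for idx, r, h in zip(members, rho_obs, hits):
            rho[idx] = r
            pperm[idx] = (1.0 + h) / (B + 1.0)

    table = pd.DataFrame(rows, columns=["gene", "guide_set", "k", "k_prime"])
    table["rho"] = rho
    table["p"] = pperm
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table.sort_values(["p", "rho", "gene", "guide_set"],
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def dedupe_gene_sets(table: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: for genes with two guide sets keep the
    higher-ranking set (smaller p; ties by smaller rho, then first set
    tag) and discard the other."""
    ordered = table.sort_values(["gene", "p", "rho", "guide_set"],
                                kind="mergesort")
    out = ordered.drop_duplicates(subset="gene", keep="first")
    out = out.sort_values(["p", "rho", "gene"], kind="mergesort")
    out = out.reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def call_hits(table: pd.DataFrame, p_threshold: float = 0.01) -> set[str]:
    """Genes with unadjusted permutation p below the threshold."""
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must lie in (0, 1]")
    return set(table.loc[table["p"] < p_threshold, "gene"])


def ranked_hits(table: pd.DataFrame, p_threshold: float = 0.01) -> pd.DataFrame:
    """Ranked hit export with the -log10(p) enrichment score."""
    hits = table[table["p"] < p_threshold].copy()
    hits["neg_log10_p"] = -np.log10(hits["p"])
    return hits.sort_values(["p", "rho", "gene"],
                            kind="mergesort").reset_index(drop=True)
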