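"""Empirical randomization tests, FDR control, and cohort comparison.

The accuracy of each gene's RBP-plus model is compared against two empirical
null schemes, each generating (by default) 1000 randomized versions of the
model that are refit by the *identical* nested-CV pipeline as the actual
fit:

* ``by_rbp`` — replace the gene's inferred RBPs by the same number of
  proteins drawn at random (without replacement) from the measured pool;
* ``by_sample`` — jointly permute the sample rows of the RBP predictor
  block, preserving inter-RBP correlation under the null.

The empirical p-value is the proportion of null accuracies strictly greater
than the actual accuracy, floored at 1/N.  A gene is called informative when
its RBP-plus accuracy exceeds its RNA-only accuracy and the by_rbp raw p is
below 0.05; Storey q-values and Benjamini-Hochberg adjustments are reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import models
from .util import logger, stable_seed


@dataclass
class NullDistribution:
    gene_id: str
    scheme: str  # "by_sample" | "by_rbp"
    null_r2: np.ndarray
    seed: int


@dataclass
class SignificanceRecord:
    gene_id: str
    scheme: str
    p_raw: float
    q_storey: float
    informative: bool


# -- multiple testing -------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def storey_qvalues(p, pi0: float | None = None, lambdas=None) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on the grid lambda in {0.05, ..., 0.95} by fitting a
    cubic smoother to pi0(lambda) = #{p > lambda} / (m (1 - lambda)) and
    evaluating it at the largest lambda (the standard qvalue procedure).
    With fewer than 10 p-values pi0 is fixed to 1 (with a warning), in which
    case -- as whenever ``pi0=1`` is forced -- the result equals the
    Benjamini-Hochberg adjustment exactly.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 10:
            logger.warning("storey_qvalues: %d p-values < 10, fixing pi0 = 1", m)
            pi0 = 1.0
        else:
            if lambdas is None:
                lambdas = np.arange(0.05, 0.96, 0.05)
            lambdas = np.asarray(lambdas, dtype=float)
            pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
            coeffs = np.polyfit(lambdas, pi0_l, deg=3)
            pi0 = float(np.polyval(coeffs, lambdas.max()))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    return np.minimum(pi0 * bh_adjust(p), 1.0)


# -- empirical nulls --------------------------------------------------------


def empirical_pvalue(actual_r2: float, null: NullDistribution | np.ndarray) -> float:
    """p = max(#{null > actual} / N, 1/N); strictly-greater, ties don't count."""
    null_r2 = null.null_r2 if isinstance(null, NullDistribution) else np.asarray(null)
    if null_r2.size == 0:
        raise ValueError("empty null distribution")
    n = null_r2.size
    return max(float((null_r2 > actual_r2).sum()) / n, 1.0 / n)


def _refit_null(y, x, X, folds, penalty, inner_k, lambda_grid, gene_id, gene_seed):
    """Single null replicate: the same code path as the actual fit."""
    fit = models.fit_rbp_plus(
        y, x, X, folds,
        penalty=penalty, inner_k=inner_k, lambda_grid=lambda_grid,
        gene_id=gene_id, seed=gene_seed,
    )
    return fit.r2


def randomize_by_sample(
    y, x_mrna, X_rbp, folds,
    n_perm: int = 1000, seed: int = 0,
    penalty: str = "ridge", inner_k: int = 5, lambda_grid=None,
    gene_id: str = "", fit_seed: int | None = None,
) -> NullDistribution:
    """Null scheme 2: permute the RBP block's sample rows jointly per replicate.

    The target protein and mRNA are untouched; the permuted model is refit by
    the identical nested-CV procedure and its held-out R^2 recorded.
    """
    if n_perm < 100:
        logger.warning("randomize_by_sample: n_perm=%d gives coarse p resolution", n_perm)
    X = np.asarray(X_rbp, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        raise ValueError("gene has no RBPs to permute")
    if lambda_grid is None:
        lambda_grid = models.default_lambda_grid(X)
    fit_seed = seed if fit_seed is None else fit_seed
    rng = np.random.default_rng(seed)
    n = len(y)
    null_r2 = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(n)
        null_r2[r] = _refit_null(
            y, x_mrna, X[perm], folds, penalty, inner_k, lambda_grid, gene_id, fit_seed
        )
    return NullDistribution(gene_id, "by_sample", null_r2, seed)


def randomize_by_rbp(
    y, x_mrna, pool: pd.DataFrame, k_rbps: int, folds,
    n_perm: int = 1000, seed: int = 0,
    penalty: str = "ridge", inner_k: int = 5, lambda_grid=None,
    gene_id: str = "", fit_seed: int | None = None,
) -> NullDistribution:
    """Null scheme 1: substitute the RBPs by random proteins from ``pool``.

    Each replicate draws, without replacement, as many pool columns as the
    gene has actual RBPs and refits by the identical pipeline.  The pool
    should exclude the target gene's own protein and its actual RBPs (see
    :func:`random_protein_pool`).  ``seed`` drives the draws; ``fit_seed``
    (defaulting to ``seed``) is the nested-CV seed of the refits and should
    match the actual fit's seed so that null models differ from the actual
    model only in their predictors.
    """
    if pool.shape[1] < k_rbps:
        raise ValueError(
            f"pool of {pool.shape[1]} proteins smaller than RBP count {k_rbps}"
        )
    if n_perm < 100:
        logger.warning("randomize_by_rbp: n_perm=%d gives coarse p resolution", n_perm)
    fit_seed = seed if fit_seed is None else fit_seed
    P = pool.values.astype(float)
    rng = np.random.default_rng(seed)
    null_r2 = np.empty(n_perm)
    for r in range(n_perm):
        cols = rng.choice(P.shape[1], size=k_rbps, replace=False)
        null_r2[r] = _refit_null(
            y, x_mrna, P[:, cols], folds, penalty, inner_k, None, gene_id, fit_seed
        )
    return NullDistribution(gene_id, "by_rbp", null_r2, seed)


def random_protein_pool(panel, gene_id: str, rbp_ids) -> pd.DataFrame:
    """Measured proteins eligible as random predictors for one gene.

    Excludes the gene's own protein (trivial self-prediction) and its actual
    RBPs; both exclusions are the default and configurable by passing a
    different frame to :func:`randomize_by_rbp`.
    """
    drop = {gene_id, *rbp_ids}
    cols = [c for c in panel.protein.columns if c not in drop]
    return panel.protein[cols]


def test_gene(
    panel, imap, gene_id: str, scheme: str,
    n_perm: int = 1000, seed: int = 0,
    penalty: str = "ridge", inner_k: int = 5, k: int = 5,
) -> NullDistribution:
    """Build the null distribution for one mapped gene of a fitted panel.

    Uses the same per-gene fold assignment (derived from the master seed and
    gene id) as :func:`rbpreg.models.fit_panel`, restricted to the gene's
    complete cases.
    """
    rbps = [r for r in imap.rbps_for(gene_id) if r != gene_id]
    y, x, X, ok = models.complete_cases(panel, gene_id, rbps)
    gene_seed = stable_seed(seed, gene_id)
    folds = models.make_folds(int(ok.sum()), k, seed=gene_seed)
    null_seed = stable_seed(seed, gene_id, scheme)
    if scheme == "by_sample":
        return randomize_by_sample(
            y[ok], x[ok], X[ok], folds, n_perm=n_perm, seed=null_seed,
            penalty=penalty, inner_k=inner_k, gene_id=gene_id, fit_seed=gene_seed,
        )
    if scheme == "by_rbp":
        pool = random_protein_pool(panel, gene_id, rbps).loc[ok]
        pool = pool.dropna(axis=1)  # pool columns must be complete on these samples
        return randomize_by_rbp(
            y[ok], x[ok], pool, len(rbps), folds, n_perm=n_perm, seed=null_seed,
            penalty=penalty, inner_k=inner_k, gene_id=gene_id, fit_seed=gene_seed,
        )
    raise ValueError(f"unknown scheme {scheme!r}")


def significance_table(pairs: pd.DataFrame, nulls: dict) -> pd.DataFrame:
    """Assemble per-gene raw p, Storey q, and the informative flag.

    ``pairs`` is the accuracy table from :func:`rbpreg.models.fit_panel`;
    ``nulls`` maps gene -> NullDistribution (one scheme).  Informative genes
    (by the by_rbp scheme) must improve on RNA-only AND have raw p < 0.05.
    """
    genes = [g for g in pairs["gene"] if g in nulls]
    sub = pairs.set_index("gene").loc[genes]
    p_raw = np.array(
        [empirical_pvalue(sub.loc[g, "r2_rbp_plus"], nulls[g]) for g in genes]
    )
    q = storey_qvalues(p_raw) if len(p_raw) else np.array([])
    scheme = nulls[genes[0]].scheme if genes else ""
    informative = (
        (sub["r2_rbp_plus"].values > sub["r2_rna_only"].values) & (p_raw < 0.05)
        if scheme == "by_rbp"
        else np.zeros(len(genes), dtype=bool)
    )
    return pd.DataFrame(
        {
            "gene": genes,
            "scheme": scheme,
            "p_raw": p_raw,
            "q_storey": q,
            "q_lt_0.05": q < 0.05,
            "informative": informative,
        }
    )


def call_informative(pairs: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Flag genes where RBPs are informative: improvement > 0 and p_raw < 0.05.

    ``records`` must come from the by_rbp scheme (the definition the call is
    tied to); q-based calls (q < 0.05) are reported alongside, not forced.
    """
    merged = pairs.merge(records[["gene", "p_raw", "q_storey"]], on="gene", how="inner")
    merged["informative"] = (merged["r2_rbp_plus"] > merged["r2_rna_only"]) & (
        merged["p_raw"] < 0.05
    )
    merged["informative_q"] = (merged["r2_rbp_plus"] > merged["r2_rna_only"]) & (
        merged["q_storey"] < 0.05
    )
    return merged


# -- cohort comparison ------------------------------------------------------


def _signed_rank_stat(d: np.ndarray):
    """(W+, ranks) for nonzero differences with average ranks for ties."""
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    return w_pos, ranks


def compare_models_wilcoxon(pairs: pd.DataFrame, exact_max_n: int = 12):
    """Two-sided Wilcoxon signed-rank test on per-gene accuracy differences.

    Differences r2_rbp_plus - r2_rna_only across genes; zeros are dropped.
    For n <= ``exact_max_n`` the p-value is computed by exact enumeration of
    all 2^n sign assignments of the (tie-averaged) ranks, doubling the
    smaller tail and capping at 1; otherwise a normal approximation with
    continuity and tie correction is used.

    Returns ``(W, p, method)``.
    """
    d = (pairs["r2_rbp_plus"] - pairs["r2_rna_only"]).values.astype(float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        logger.warning("compare_models_wilcoxon: all differences zero")
        return 0.0, 1.0, "degenerate"
    if n < 6:
        logger.warning("compare_models_wilcoxon: only %d nonzero differences", n)
    w_pos, ranks = _signed_rank_stat(d)
    if n <= exact_max_n:
        # distribution of W+ over all sign assignments, by subset-sum DP on
        # twice the ranks (integers even with .5 average ranks)
        ints = np.rint(2 * ranks).astype(int)
        total = ints.sum()
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in ints:
            counts[r:] += counts[: total + 1 - r].copy()
        counts /= counts.sum()
        obs = int(round(2 * w_pos))
        p_le = counts[: obs + 1].sum()
        p_ge = counts[obs:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_pos, float(p), "exact"
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    diff = w_pos - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return w_pos, min(p, 1.0), "normal"
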