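"""Per-gene dual regression models under nested cross-validation.

For every modelled gene j with protein abundance PROT_ij and transcript
abundance mRNA_ij across samples i, two models are compared:

* RNA-only:  PROT_ij = b0_j + bm_j * mRNA_ij + e_ij            (plain OLS)
* RBP-plus:  PROT_ij = b0_j + bm_j * mRNA_ij
                         + sum_k bR_jk * RBP_ik + e_ij

where RBP_ik are the measured protein levels of the RBPs inferred to bind
gene j's UTRs.  The RBP block is penalized (ridge or lasso); the intercept
and the mRNA coefficient are *exactly* unpenalized, so with an infinite
penalty the RBP-plus model collapses onto the RNA-only model.  The penalty
weight is tuned by inner cross-validation within each outer training split
(nested CV); prediction accuracy is the R^2 of the pooled held-out
predictions, 1 - SSE/SST, which can be negative out of sample.

The unpenalized block is handled by exact profiling: minimizing
||y - U a - X b||^2 + lambda * P(b) over ``a`` for fixed ``b`` shows the
penalized coefficients solve the same problem on U-residualized y and X.
This makes the whole ridge lambda path a single eigendecomposition per
training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import logger, stable_seed

DEFAULT_GRID_POINTS = 50
DEFAULT_GRID_RANGE = (1e-4, 1e4)


class DegenerateFitError(ValueError):
    pass


def r_squared(y, f) -> float:
    """R^2 = 1 - sum (y_i - f_i)^2 / sum (y_i - <y>)^2.

    Defined for len >= 2 and non-constant y; negative values mean the
    predictions do worse than the observation mean.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or y.size < 2:
        raise ValueError("y and f must have equal length >= 2")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise DegenerateFitError("constant observations: R^2 undefined")
    sse = float(((y - f) ** 2).sum())
    return 1.0 - sse / sst


def make_folds(n_samples: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random k-fold partition; sizes differ by at most one; deterministic."""
    if n_samples < k:
        raise ValueError(f"n_samples={n_samples} < k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    assignment = np.empty(n_samples, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = f
    return assignment


def default_lambda_grid(X: np.ndarray) -> np.ndarray:
    """Shared penalty grid: 49 log-spaced points on [1e-4, 1e4] scaled by the
    mean RBP-column variance, plus an exact infinite-penalty point.

    The infinite point makes the RBP-plus family nest the RNA-only model
    exactly, which is the convergence contract for uninformative RBPs.
    """
    X = np.asarray(X, dtype=float)
    scale = 1.0
    if X.size:
        v = X.var(axis=0).mean()
        if v > 0:
            scale = float(v)
    lo, hi = DEFAULT_GRID_RANGE
    finite = np.geomspace(lo, hi, DEFAULT_GRID_POINTS - 1) * scale
    return np.concatenate([finite, [np.inf]])


@dataclass
class GeneModelFit:
    """One fitted model (RNA-only or RBP-plus) for one gene."""

    gene_id: str
    beta0: float
    beta_mrna: float
    beta_rbp: pd.Series  # empty for RNA-only
    penalty: str  # "ridge" | "lasso" | "none"
    lambda_: float | None  # penalty chosen on the full data (None for OLS)
    lambda_per_fold: list = field(default_factory=list)
    residual_sd: float = float("nan")
    cv_predictions: pd.Series | None = None
    r2: float = float("nan")
    fold_assignment: np.ndarray | None = None
    seed: int = 0
    warnings: list = field(default_factory=list)


@dataclass
class AccuracyPair:
    gene_id: str
    r2_rna_only: float
    r2_rbp_plus: float

    @property
    def improvement(self) -> float:
        return self.r2_rbp_plus - self.r2_rna_only


# -- core solvers -----------------------------------------------------------


def _residualize(U: np.ndarray, y: np.ndarray, X: np.ndarray):
    """Project y and X off the column space of U (exact profiling step)."""
    Q, _ = np.linalg.qr(U)
    My = y - Q @ (Q.T @ y)
    MX = X - Q @ (Q.T @ X) if X.size else X
    return Q, My, MX


def _unpenalized_coefs(U: np.ndarray, y: np.ndarray, X: np.ndarray, B: np.ndarray):
    """OLS of (y - X B) on U, for each column of B. Returns (U_cols x L)."""
    resid = y[:, None] - (X @ B if X.size else 0.0)
    A, *_ = np.linalg.lstsq(U, resid, rcond=None)
    return A


def _ridge_path(My: np.ndarray, MX: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Ridge coefficients of the residualized block for every lambda.

    Returns B of shape (k, L); infinite lambdas give exact zero columns.
    """
    k = MX.shape[1]
    B = np.zeros((k, len(lambdas)))
    finite = np.isfinite(lambdas)
    if k and finite.any():
        G = MX.T @ MX
        w, V = np.linalg.eigh(G)
        c = V.T @ (MX.T @ My)
        lam = lambdas[finite]
        B[:, finite] = V @ (c[:, None] / (w[:, None] + lam[None, :]))
    return B


def _lasso_path(My: np.ndarray, MX: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Lasso coefficients of the residualized block for every lambda.

    Objective ||r||^2 + lambda * ||b||_1; delegates to sklearn's coordinate
    descent path (alpha = lambda / (2 n)).  Infinite lambdas give exact
    zeros.
    """
    from sklearn.linear_model import lasso_path

    k = MX.shape[1]
    B = np.zeros((k, len(lambdas)))
    finite = np.isfinite(lambdas)
    if k and finite.any():
        n = len(My)
        alphas = lambdas[finite] / (2.0 * n)
        order = np.argsort(alphas)[::-1]  # sklearn wants decreasing alphas
        _, coefs, _ = lasso_path(MX, My, alphas=alphas[order], tol=1e-10, max_iter=100000)
        out = np.empty_like(coefs)
        out[:, order] = coefs
        B[:, finite] = out
    return B


def _path_coefs(My, MX, lambdas, penalty):
    if penalty == "ridge":
        return _ridge_path(My, MX, lambdas)
    if penalty == "lasso":
        return _lasso_path(My, MX, lambdas)
    raise ValueError(f"unknown penalty {penalty!r}")


def _choose_lambda(sse: np.ndarray, lambdas: np.ndarray) -> int:
    """Index of the inner-CV-optimal lambda; ties go to the largest lambda."""
    rev = sse[::-1]
    return len(lambdas) - 1 - int(np.argmin(rev))


# -- model fits -------------------------------------------------------------


def fit_rna_only(y, x_mrna, folds, gene_id: str = "", seed: int = 0) -> GeneModelFit:
    """Simple linear regression protein ~ mRNA with k-fold held-out R^2.

    ``y`` and ``x_mrna`` must be complete (the caller handles missingness);
    ``folds`` assigns each sample to an outer fold.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_mrna, dtype=float)
    folds = np.asarray(folds)
    preds = np.full(len(y), np.nan)
    warns: list[str] = []
    for f in np.unique(folds):
        tr = folds != f
        te = ~tr
        if tr.sum() < 4:
            raise DegenerateFitError(f"gene {gene_id}: <4 training samples in fold {f}")
        if np.ptp(x[tr]) == 0:
            warns.append(f"fold {int(f)}: constant mRNA in training split, fold skipped")
            continue
        U = np.column_stack([np.ones(tr.sum()), x[tr]])
        beta, *_ = np.linalg.lstsq(U, y[tr], rcond=None)
        preds[te] = beta[0] + beta[1] * x[te]
    ok = np.isfinite(preds)
    r2 = r_squared(y[ok], preds[ok]) if ok.sum() >= 2 else float("nan")
    Uall = np.column_stack([np.ones(len(y)), x])
    ball, *_ = np.linalg.lstsq(Uall, y, rcond=None)
    resid = y - Uall @ ball
    dof = max(len(y) - 2, 1)
    return GeneModelFit(
        gene_id=gene_id,
        beta0=float(ball[0]),
        beta_mrna=float(ball[1]),
        beta_rbp=pd.Series(dtype=float),
        penalty="none",
        lambda_=None,
        residual_sd=float(np.sqrt(resid @ resid / dof)),
        cv_predictions=pd.Series(preds),
        r2=r2,
        fold_assignment=folds,
        seed=seed,
        warnings=warns,
    )


def fit_rbp_plus(
    y,
    x_mrna,
    X_rbp,
    folds,
    penalty: str = "ridge",
    inner_k: int = 5,
    lambda_grid=None,
    gene_id: str = "",
    seed: int = 0,
    rbp_ids=None,
) -> GeneModelFit:
    """Penalized multiple regression with unpenalized intercept + mRNA.

    For each outer fold the penalty weight is chosen on a shared lambda grid
    by ``inner_k``-fold CV within the training split only (no leakage), the
    model is refit on the whole training split at that lambda, and the
    held-out samples are predicted.  Reported coefficients come from a final
    fit on all samples with lambda tuned the same way.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_mrna, dtype=float)
    X = np.asarray(X_rbp, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    folds = np.asarray(folds)
    if X.shape[1] == 0:
        logger.info("gene %s: empty RBP block, falling back to RNA-only", gene_id)
        fit = fit_rna_only(y, x, folds, gene_id=gene_id, seed=seed)
        fit.warnings.append("empty RBP block: RNA-only fallback")
        return fit
    if rbp_ids is None:
        rbp_ids = [f"rbp{i}" for i in range(X.shape[1])]
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    def tune(idx: np.ndarray, fold_tag) -> float:
        """Inner-CV lambda selection restricted to samples ``idx``."""
        n_tr = len(idx)
        if n_tr < inner_k + 1:
            raise DegenerateFitError(
                f"gene {gene_id}: {n_tr} training samples < inner_k+1={inner_k + 1}"
            )
        inner = make_folds(n_tr, inner_k, seed=stable_seed(seed, gene_id, "inner", fold_tag))
        sse = np.zeros(len(lambda_grid))
        for g in np.unique(inner):
            itr = idx[inner != g]
            ite = idx[inner == g]
            U = np.column_stack([np.ones(len(itr)), x[itr]])
            _, My, MX = _residualize(U, y[itr], X[itr])
            B = _path_coefs(My, MX, lambda_grid, penalty)
            A = _unpenalized_coefs(U, y[itr], X[itr], B)
            Ute = np.column_stack([np.ones(len(ite)), x[ite]])
            pred = Ute @ A + X[ite] @ B
            sse += ((y[ite][:, None] - pred) ** 2).sum(axis=0)
        return _choose_lambda(sse, lambda_grid)

    def solve(idx: np.ndarray, lam_idx: int):
        lam = lambda_grid[lam_idx : lam_idx + 1]
        U = np.column_stack([np.ones(len(idx)), x[idx]])
        _, My, MX = _residualize(U, y[idx], X[idx])
        B = _path_coefs(My, MX, lam, penalty)
        A = _unpenalized_coefs(U, y[idx], X[idx], B)
        return A[:, 0], B[:, 0]

    preds = np.full(len(y), np.nan)
    lam_per_fold = []
    for f in np.unique(folds):
        tr_idx = np.flatnonzero(folds != f)
        te_idx = np.flatnonzero(folds == f)
        lam_idx = tune(tr_idx, int(f))
        a, b = solve(tr_idx, lam_idx)
        preds[te_idx] = a[0] + a[1] * x[te_idx] + X[te_idx] @ b
        lam_per_fold.append(float(lambda_grid[lam_idx]))
    r2 = r_squared(y, preds)

    all_idx = np.arange(len(y))
    lam_idx_final = tune(all_idx, "final")
    a_fin, b_fin = solve(all_idx, lam_idx_final)
    resid = y - (a_fin[0] + a_fin[1] * x + X @ b_fin)
    dof = max(len(y) - 2, 1)
    return GeneModelFit(
        gene_id=gene_id,
        beta0=float(a_fin[0]),
        beta_mrna=float(a_fin[1]),
        beta_rbp=pd.Series(b_fin, index=list(rbp_ids)),
        penalty=penalty,
        lambda_=float(lambda_grid[lam_idx_final]),
        lambda_per_fold=lam_per_fold,
        residual_sd=float(np.sqrt(resid @ resid / dof)),
        cv_predictions=pd.Series(preds),
        r2=r2,
        fold_assignment=folds,
        seed=seed,
    )


def compute_improvement(fit_rna: GeneModelFit, fit_rbp: GeneModelFit) -> AccuracyPair:
    """Accuracy difference R^2(RBP-plus) - R^2(RNA-only) for one gene."""
    if fit_rna.gene_id != fit_rbp.gene_id:
        raise ValueError("fits describe different genes")
    if not np.array_equal(fit_rna.fold_assignment, fit_rbp.fold_assignment):
        raise ValueError("fold assignments differ: accuracies not comparable")
    return AccuracyPair(fit_rna.gene_id, fit_rna.r2, fit_rbp.r2)


def complete_cases(panel, gene_id: str, rbp_ids):
    """Sample mask where target protein, mRNA, and all used RBPs are observed."""
    y = panel.protein[gene_id].values.astype(float)
    x = panel.mrna[gene_id].values.astype(float)
    X = panel.protein[list(rbp_ids)].values.astype(float) if rbp_ids else np.empty((len(y), 0))
    ok = np.isfinite(y) & np.isfinite(x)
    if X.size:
        ok &= np.isfinite(X).all(axis=1)
    return y, x, X, ok


def fit_panel(
    panel,
    imap,
    penalty: str = "ridge",
    seed: int = 0,
    k: int = 5,
    inner_k: int = 5,
    lambda_grid=None,
):
    """Fit RNA-only and RBP-plus models for every mapped gene of a panel.

    The panel must be detection-filtered and mean-centred, and the map
    restricted to measured RBPs.  Both models of a gene share one fold
    assignment (per-gene seed derived from the master seed and gene id).

    Returns ``(accuracy_frame, fits)``: a table with one row per modelled
    gene and a dict gene -> (rna_fit, rbp_fit).
    """
    rows = []
    fits = {}
    skipped = []
    for gene in imap.transcripts():
        if gene not in panel.protein.columns or gene not in panel.mrna.columns:
            skipped.append(gene)
            continue
        rbps = [r for r in imap.rbps_for(gene) if r != gene]
        y, x, X, ok = complete_cases(panel, gene, rbps)
        if ok.sum() < max(k, 6):
            skipped.append(gene)
            continue
        gene_seed = stable_seed(seed, gene)
        folds = make_folds(int(ok.sum()), k, seed=gene_seed)
        try:
            f_rna = fit_rna_only(y[ok], x[ok], folds, gene_id=gene, seed=gene_seed)
            f_rbp = fit_rbp_plus(
                y[ok], x[ok], X[ok], folds,
                penalty=penalty, inner_k=inner_k, lambda_grid=lambda_grid,
                gene_id=gene, seed=gene_seed, rbp_ids=rbps,
            )
        except DegenerateFitError as err:
            logger.warning("gene %s skipped: %s", gene, err)
            skipped.append(gene)
            continue
        pair = compute_improvement(f_rna, f_rbp)
        fits[gene] = (f_rna, f_rbp)
        rows.append(
            (
                gene, pair.r2_rna_only, pair.r2_rbp_plus, pair.improvement,
                len(rbps), penalty,
                ";".join(f"{v:.6g}" for v in f_rbp.lambda_per_fold),
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene", "r2_rna_only", "r2_rbp_plus", "improvement",
            "n_rbps", "penalty", "lambda_per_fold",
        ],
    )
    if skipped:
        logger.info("fit_panel: skipped %d genes (insufficient data)", len(skipped))
    return frame, fits
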