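"""RBP prioritization by uTIS proximity and cross-panel model transfer.

If an RBP exerts translational control through an upstream initiation site,
its binding site should sit near that uTIS.  For every informative gene we
therefore assign each uTIS to the retained 5'UTR binding site nearest to
it, and rank RBPs by the number of genes where they own at least one
nearest site.

Model transferability is assessed by training RBP-plus models on all
samples of one panel (restricted to RBPs measured in both panels), applying
them unchanged to a second panel, and correlating the resulting per-gene
test accuracies with those of models trained on the test panel itself
(Spearman).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import models
from .util import logger, stable_seed


def _edge_distance(utis: int, start: int, end: int) -> int:
    """nt separation between a uTIS first base and a site's nearest boundary.

    Zero when the uTIS lies inside the half-open interval [start, end); the
    half-open end coordinate is treated as the downstream boundary.
    """
    return max(0, start - utis, utis - end)


def nearest_site_per_utis(hits, utis_offsets):
    """Assign each uTIS to the closest retained 5'UTR binding site.

    ``hits`` is an iterable of MotifHit (only region == "5UTR" entries are
    used).  Ties are broken by smaller site start, then lexicographic RBP id.
    Returns a list of ``(utis_offset, rbp_id, distance)``; empty when the
    gene has no 5'UTR hits.
    """
    sites = sorted(
        ((h.start, h.rbp_id, h.end) for h in hits if h.region == "5UTR"),
        key=lambda s: (s[0], s[1]),
    )
    if not sites:
        return []
    out = []
    for u in utis_offsets:
        best = min(sites, key=lambda s: (_edge_distance(u, s[0], s[2]), s[0], s[1]))
        out.append((u, best[1], _edge_distance(u, best[0], best[2])))
    return out


@dataclass
class PriorityTable:
    table: pd.DataFrame  # rbp, n_genes, pct, rank
    n_eligible: int
    n_skipped: int


def prioritize_rbps(informative_genes, imap, annotations) -> PriorityTable:
    """Rank RBPs by how often they own the binding site nearest to a uTIS.

    Eligible genes are informative genes with at least one retained 5'UTR
    hit and at least one uTIS; a gene contributes once to each RBP that owns
    the nearest site of at least one of its uTISs.  Percentages are over
    eligible genes; ordering is by count descending, then RBP id.
    """
    counts: dict[str, int] = {}
    n_eligible = 0
    n_skipped = 0
    for gene in sorted(set(informative_genes)):
        ann = annotations.get(gene)
        rbp_hits = imap.targets.get(gene, {})
        hits = [h for hl in rbp_hits.values() for h in hl]
        utis = [u.offset for u in ann.utis_list] if ann is not None else []
        assigned = nearest_site_per_utis(hits, utis) if utis else []
        if not assigned:
            n_skipped += 1
            continue
        n_eligible += 1
        for rbp in {rbp for _, rbp, _ in assigned}:
            counts[rbp] = counts.get(rbp, 0) + 1
    if not counts:
        logger.warning("prioritize_rbps: no eligible informative genes")
        table = pd.DataFrame(columns=["rbp", "n_genes", "pct", "rank"])
        return PriorityTable(table, n_eligible, n_skipped)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(rows, columns=["rbp", "n_genes"])
    table["pct"] = 100.0 * table["n_genes"] / n_eligible
    table["rank"] = np.arange(1, len(table) + 1)
    return PriorityTable(table, n_eligible, n_skipped)


# -- cross-panel transfer ---------------------------------------------------


def _whole_panel_fit(panel, gene, rbps, penalty, inner_k, seed):
    """Fit an RBP-plus model on all complete samples of a panel (no outer CV);
    the penalty is still tuned by inner CV within the panel."""
    y, x, X, ok = models.complete_cases(panel, gene, rbps)
    n = int(ok.sum())
    if n < inner_k + 2:
        return None
    lambda_grid = models.default_lambda_grid(X[ok]) if rbps else None
    gene_seed = stable_seed(seed, gene, "transfer")
    if rbps:
        fit = models.fit_rbp_plus(
            y[ok], x[ok], X[ok], np.arange(n) % inner_k,
            penalty=penalty, inner_k=inner_k, lambda_grid=lambda_grid,
            gene_id=gene, seed=gene_seed, rbp_ids=rbps,
        )
    else:
        fit = models.fit_rna_only(y[ok], x[ok], np.arange(n) % inner_k, gene_id=gene, seed=gene_seed)
    return fit


def _apply_fit(fit, panel, gene, rbps):
    """Evaluate a fitted model on all complete samples of ``panel``."""
    y, x, X, ok = models.complete_cases(panel, gene, rbps)
    if ok.sum() < 3:
        return None
    beta_rbp = fit.beta_rbp.reindex(rbps).fillna(0.0).values if rbps else np.zeros(0)
    pred = fit.beta0 + fit.beta_mrna * x[ok]
    if len(rbps):
        pred = pred + X[ok] @ beta_rbp
    try:
        return models.r_squared(y[ok], pred)
    except models.DegenerateFitError:
        return None


def cross_panel_transfer(
    train_panel, train_map, test_panel,
    penalty: str = "ridge", inner_k: int = 5, seed: int = 0,
):
    """Train on one panel, test on another, and score transferability.

    Models are trained on *all* samples of the training panel using only the
    RBPs measured in both panels (penalty tuned by inner CV within the
    training panel) and applied unchanged to the test panel.  Genes with no
    shared RBPs fall back to RNA-only and are flagged.  Transferability is
    the Spearman correlation between the test-panel accuracies of the
    transferred models and of models trained on the test panel itself.

    Returns a dict report with the per-gene accuracy frame and rho/p.
    """
    shared_rbp_universe = (
        set(train_panel.protein.columns) & set(train_panel.mrna.columns)
        & set(test_panel.protein.columns) & set(test_panel.mrna.columns)
    )
    shared_genes = [
        g for g in train_map.transcripts()
        if g in train_panel.protein.columns and g in test_panel.protein.columns
        and g in train_panel.mrna.columns and g in test_panel.mrna.columns
    ]
    if not shared_genes:
        raise ValueError("no genes shared between the training map and the test panel")
    rows = []
    n_fallback = n_skipped = n_transferred = 0
    for gene in shared_genes:
        all_rbps = [r for r in train_map.rbps_for(gene) if r != gene]
        rbps = [r for r in all_rbps if r in shared_rbp_universe]
        fallback = bool(all_rbps) and not rbps
        if fallback:
            n_fallback += 1
            logger.info("transfer: gene %s has no shared RBPs, RNA-only fallback", gene)
        # same seed derivation for both fits: identical panels then yield
        # identical models, so self-transfer scores rho = 1 exactly
        fit_train = _whole_panel_fit(train_panel, gene, rbps, penalty, inner_k, seed)
        fit_test = _whole_panel_fit(test_panel, gene, rbps, penalty, inner_k, seed)
        if fit_train is None or fit_test is None:
            n_skipped += 1
            continue
        acc_transfer = _apply_fit(fit_train, test_panel, gene, rbps)
        acc_native = _apply_fit(fit_test, test_panel, gene, rbps)
        if acc_transfer is None or acc_native is None:
            n_skipped += 1
            continue
        n_transferred += 1
        rows.append((gene, len(rbps), acc_transfer, acc_native, fallback))
    frame = pd.DataFrame(
        rows, columns=["gene", "n_shared_rbps", "r2_transfer", "r2_native", "rna_only_fallback"]
    )
    if len(frame) >= 3 and frame["r2_transfer"].nunique() > 1 and frame["r2_native"].nunique() > 1:
        rho, p = stats.spearmanr(frame["r2_transfer"], frame["r2_native"])
    else:
        rho, p = float("nan"), float("nan")
    return {
        "accuracies": frame,
        "rho": float(rho),
        "p": float(p),
        "n_shared_genes": len(shared_genes),
        "n_shared_rbps": len(shared_rbp_universe),
        "n_transferred": n_transferred,
        "n_fallback": n_fallback,
        "n_skipped": n_skipped,
    }
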