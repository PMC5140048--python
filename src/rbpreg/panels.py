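"""Matched transcriptome/proteome panels: loading, detection filtering,
per-sample mean-centring, and influence diagnostics.

A panel holds two log-scale abundance matrices (samples x genes) over a
shared sample set: transcript abundance (e.g. log10 FPKM) and protein
abundance (e.g. log10 iBAQ or spectral counts).  Values below the detection
limit are encoded as missing (NaN); zeros in the input files are treated as
below detection.  All downstream modelling operates on the observed entries
only -- nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import logger


class PanelFormatError(ValueError):
    """Raised for malformed or incompatible panel files."""


class EmptyPanelError(ValueError):
    """Raised when filtering removes every gene."""


@dataclass
class ExpressionPanel:
    """Matched samples x genes mRNA and protein abundance matrices.

    Both frames share the same sample index; columns may differ (proteome
    coverage is typically a subset of the transcriptome).  NaN marks entries
    below the detection limit.
    """

    mrna: pd.DataFrame
    protein: pd.DataFrame
    meta: str = ""

    def __post_init__(self) -> None:
        if not self.mrna.index.equals(self.protein.index):
            raise PanelFormatError("mRNA and protein matrices must share samples")

    @property
    def sample_ids(self) -> list:
        return list(self.mrna.index)

    @property
    def gene_ids(self) -> list:
        return list(self.mrna.columns)

    @property
    def detected_mrna(self) -> pd.DataFrame:
        return self.mrna.notna()

    @property
    def detected_protein(self) -> pd.DataFrame:
        return self.protein.notna()

    def copy(self) -> "ExpressionPanel":
        return ExpressionPanel(self.mrna.copy(), self.protein.copy(), self.meta)


def _read_matrix(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set = set()
    for g in header:  # pandas silently renames duplicate columns; check raw header
        if g in seen:
            raise PanelFormatError(f"duplicate gene ID {g!r} in {path}")
        seen.add(g)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise PanelFormatError(f"duplicate sample ID {dup!r} in {path}")
    df = df.apply(pd.to_numeric, errors="coerce")
    # zeros are below-detection sentinels in the source files
    return df.mask(df == 0.0)


def load_panel(mrna_path, protein_path, meta: str = "") -> ExpressionPanel:
    """Load a panel from two TSV files (samples as rows, first column = ID).

    The panel is restricted to samples present in both files, preserving the
    order of the mRNA file.  Empty cells and exact zeros are marked
    undetected.
    """
    mrna = _read_matrix(mrna_path)
    protein = _read_matrix(protein_path)
    shared = [s for s in mrna.index if s in set(protein.index)]
    if not shared:
        raise PanelFormatError("no samples shared between mRNA and protein files")
    dropped = [s for s in mrna.index if s not in set(shared)] + [
        s for s in protein.index if s not in set(shared)
    ]
    if dropped:
        logger.info("load_panel: dropped %d unmatched samples: %s", len(dropped), dropped)
    return ExpressionPanel(mrna.loc[shared], protein.loc[shared], meta=meta)


def default_max_missing(n_samples: int) -> int:
    """Detection-filter default: 3 for panels of <= 12 samples, else 5."""
    return 3 if n_samples <= 12 else 5


def filter_detected(panel: ExpressionPanel, max_missing: int | None = None):
    """Keep genes adequately detected at BOTH the mRNA and the protein level.

    A gene is retained when its undetected-sample count is <= ``max_missing``
    in each matrix; genes absent from either matrix are excluded.  Returns
    ``(filtered_panel, retained_ids, excluded_ids)``.
    """
    n = len(panel.sample_ids)
    if max_missing is None:
        max_missing = default_max_missing(n)
    if max_missing >= n:
        raise ValueError(f"max_missing={max_missing} must be < n_samples={n}")
    shared = [g for g in panel.mrna.columns if g in set(panel.protein.columns)]
    miss_m = panel.mrna[shared].isna().sum(axis=0)
    miss_p = panel.protein[shared].isna().sum(axis=0)
    retained = [g for g in shared if miss_m[g] <= max_missing and miss_p[g] <= max_missing]
    excluded = [g for g in panel.gene_ids if g not in set(retained)] + [
        g for g in panel.protein.columns if g not in set(panel.mrna.columns)
    ]
    if not retained:
        raise EmptyPanelError("detection filter excluded every gene")
    logger.info(
        "filter_detected: retained %d / %d genes (max_missing=%d)",
        len(retained), len(shared), max_missing,
    )
    out = ExpressionPanel(panel.mrna[retained].copy(), panel.protein[retained].copy(), panel.meta)
    return out, retained, excluded


def mean_center(panel: ExpressionPanel) -> ExpressionPanel:
    """Mean-centre each sample row of both matrices over observed entries.

    Inter-sample normalization: removes per-sample global shifts so that
    average abundance cannot contribute to prediction.  Undetected entries
    are untouched.  Idempotent.
    """
    out = panel.copy()
    for name, df in (("mrna", out.mrna), ("protein", out.protein)):
        counts = df.notna().sum(axis=1)
        empty = counts[counts == 0]
        if len(empty):
            raise ValueError(
                f"sample {empty.index[0]!r} has no observed {name} entries; cannot centre"
            )
        df.iloc[:, :] = df.values - np.nanmean(df.values, axis=1, keepdims=True)
    return out


def cooks_distance_map(panel: ExpressionPanel, min_obs: int = 4):
    """Per-sample Cook's distances for each gene's protein ~ mRNA regression.

    For every gene with both measurements, fits the simple linear regression
    of protein on mRNA over complete cases and reports each sample's Cook's
    distance D_i = e_i^2 h_i / (p * s^2 * (1 - h_i)^2), p = 2.  Genes with
    fewer than ``min_obs`` complete observations are flagged and left NaN.
    Intended for reporting influential observations, not for removal.

    Returns ``(distances, flagged)`` where ``distances`` is a samples x genes
    DataFrame and ``flagged`` lists under-observed genes.
    """
    shared = [g for g in panel.mrna.columns if g in set(panel.protein.columns)]
    dist = pd.DataFrame(np.nan, index=panel.mrna.index, columns=shared)
    flagged: list[str] = []
    for g in shared:
        x = panel.mrna[g].values.astype(float)
        y = panel.protein[g].values.astype(float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < min_obs or np.ptp(x[ok]) == 0:
            flagged.append(g)
            continue
        xo, yo = x[ok], y[ok]
        X = np.column_stack([np.ones(n), xo])
        beta, *_ = np.linalg.lstsq(X, yo, rcond=None)
        resid = yo - X @ beta
        sse = float(resid @ resid)
        if n <= 2:
            flagged.append(g)
            continue
        s2 = sse / (n - 2)
        xc = xo - xo.mean()
        h = 1.0 / n + xc**2 / float(xc @ xc)
        if s2 == 0:
            d = np.zeros(n)
        else:
            d = resid**2 * h / (2.0 * s2 * (1.0 - h) ** 2)
        dist.loc[ok, g] = d
    return dist, flagged
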