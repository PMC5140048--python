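"""Transcript features and their association with model-accuracy improvement.

Derives the sequence features the analysis interrogates -- upstream
translation initiation sites (uTISs), upstream open reading frames (uORFs),
and translation-initiation context patterns around the annotated start
codon -- and tests their association with the per-gene improvement
R^2(RBP-plus) - R^2(RNA-only) by Spearman correlation, Fisher's exact test
and hypergeometric set enrichment.

Conventions (all configurable where noted):

* coordinates are 0-based; a uTIS is located by the offset of its first
  base within the 5'UTR; the annotated TIS (aTIS) sits at transcript offset
  len(5'UTR);
* uTIS distance to the aTIS is the difference of first-base offsets, in nt;
* a uORF spans its start codon through its stop codon inclusive and must be
  at least 9 nt long.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signif import bh_adjust
from .util import logger

STOP_CODONS = {"UAA", "UAG", "UGA"}
CANONICAL_START = "AUG"
#: near-cognate start codons recognized when deriving uTISs from sequence
NEAR_COGNATE_STARTS = ("CUG", "GUG", "UUG", "ACG", "AUA", "AUU", "AUC")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "M": "AC", "K": "GU", "S": "CG", "W": "AU",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


@dataclass
class UTIS:
    offset: int  # within the 5'UTR, first base, 0-based
    codon: str
    canonical: bool


@dataclass
class UORF:
    start: int  # transcript offset of the uTIS first base
    stop_end: int  # transcript offset one past the stop codon's last base
    frame_class: str  # "out_of_frame" | "in_frame_pre" | "in_frame_post"

    @property
    def length(self) -> int:
        return self.stop_end - self.start


@dataclass
class TranscriptAnnotation:
    """5'UTR/CDS/3'UTR sequences plus uTIS annotations for one transcript."""

    transcript_id: str
    utr5: str
    cds: str
    utr3: str
    utis_list: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.cds) % 3 != 0 or not self.cds.startswith(CANONICAL_START):
            raise ValueError(
                f"{self.transcript_id}: CDS must begin AUG and have length divisible by 3"
            )
        for u in self.utis_list:
            if not 0 <= u.offset < len(self.utr5):
                raise ValueError(f"{self.transcript_id}: uTIS offset {u.offset} outside 5'UTR")

    @property
    def atis(self) -> int:
        """Transcript offset of the annotated start codon's first base."""
        return len(self.utr5)

    @property
    def transcript_seq(self) -> str:
        return self.utr5 + self.cds + self.utr3


def count_utis(
    annotation: TranscriptAnnotation,
    max_distance: float = math.inf,
    canonical_filter: str = "all",
) -> int:
    """Count uTISs within ``max_distance`` nt upstream of the aTIS.

    Distance is aTIS offset minus uTIS offset (first bases).  The codon
    class filter selects canonical (AUG), non-canonical, or all uTISs.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be non-negative")
    if canonical_filter not in ("all", "canonical", "noncanonical"):
        raise ValueError(f"unknown canonical_filter {canonical_filter!r}")
    n = 0
    for u in annotation.utis_list:
        if annotation.atis - u.offset > max_distance:
            continue
        if canonical_filter == "canonical" and not u.canonical:
            continue
        if canonical_filter == "noncanonical" and u.canonical:
            continue
        n += 1
    return n


def _in_frame_stops(seq: str, start: int):
    """Transcript offsets of stop codons read in frame from ``start``."""
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            yield i


def detect_uorfs(
    annotation: TranscriptAnnotation,
    min_len: int = 9,
    start_codons=None,
) -> list[UORF]:
    """Derive uORFs from the annotated uTISs by the two-rule definition.

    Rule (i): an out-of-frame uTIS with an in-frame stop codon downstream of
    it and a span of at least ``min_len`` nt (start through stop inclusive).
    Rule (ii): an in-frame uTIS whose reading frame terminates before the
    main start codon, or only strictly after the main stop codon (an
    N-terminal-extension-like ORF, kept as printed in the defining rules).
    The minimum length applies to every uORF.

    uTIS entries whose codon is not in the accepted start set are skipped
    with a notice.
    """
    if start_codons is None:
        start_codons = {CANONICAL_START, *NEAR_COGNATE_STARTS}
    seq = annotation.transcript_seq
    atis = annotation.atis
    main_stop_start = atis + len(annotation.cds) - 3
    out: list[UORF] = []
    for u in annotation.utis_list:
        if u.codon not in start_codons:
            logger.info(
                "%s: uTIS codon %s at %d not in start set, skipped",
                annotation.transcript_id, u.codon, u.offset,
            )
            continue
        start = u.offset
        frame = (atis - start) % 3
        stops = list(_in_frame_stops(seq, start))
        if frame != 0:
            if stops:
                stop_end = stops[0] + 3
                if stop_end - start >= min_len:
                    out.append(UORF(start, stop_end, "out_of_frame"))
        else:
            pre = [s for s in stops if s + 3 <= atis]
            post = [s for s in stops if s >= main_stop_start + 3]
            if pre:
                stop_end = pre[0] + 3
                if stop_end - start >= min_len:
                    out.append(UORF(start, stop_end, "in_frame_pre"))
            elif post:
                stop_end = post[0] + 3
                if stop_end - start >= min_len:
                    out.append(UORF(start, stop_end, "in_frame_post"))
    return out


def iupac_match(pattern: str, seq: str) -> bool:
    if len(pattern) != len(seq):
        return False
    return all(s in IUPAC[p] for p, s in zip(pattern, seq))


KOZAK_PATTERN = "GCCRCCAUGG"
TIS_MOTIF_PATTERN = "RYMRMVAUGGC"


def match_tis_patterns(annotation: TranscriptAnnotation) -> dict:
    """Flags for initiation-context patterns centred on the aTIS.

    Evaluates (i) the Kozak consensus GCCRCCAUGG, (ii) the -3R/+4G minimal
    context (+1 = A of the AUG), and (iii) the FACS-seq-derived TIS motif
    RYMRMVAUGGC.  Flags whose window is truncated by a short UTR/CDS are
    ``None`` (undefined) and logged.
    """
    utr5, cds = annotation.utr5, annotation.cds
    flags: dict[str, int | None] = {}
    # Kozak spans -6..+4 -> 6 nt of UTR + AUG + 1 nt of CDS tail
    if len(utr5) >= 6 and len(cds) >= 4:
        flags["kozak_match"] = int(iupac_match(KOZAK_PATTERN, utr5[-6:] + cds[:4]))
    else:
        flags["kozak_match"] = None
    if len(utr5) >= 3 and len(cds) >= 4:
        flags["minus3R_plus4G"] = int(utr5[-3] in "AG" and cds[3] == "G")
    else:
        flags["minus3R_plus4G"] = None
    # TIS motif spans -6..+5
    if len(utr5) >= 6 and len(cds) >= 5:
        flags["tis_motif_match"] = int(iupac_match(TIS_MOTIF_PATTERN, utr5[-6:] + cds[:5]))
    else:
        flags["tis_motif_match"] = None
    if any(v is None for v in flags.values()):
        logger.info("%s: truncated aTIS context window, flags undefined", annotation.transcript_id)
    return flags


def feature_table(annotations: dict, distance_grid=(50, 100, 150, 200, 250, 300)) -> pd.DataFrame:
    """Per-gene derived feature table (lengths, uTIS counts, uORFs, TIS flags)."""
    rows = {}
    for tid, ann in annotations.items():
        flags = match_tis_patterns(ann)
        row = {
            "utr5_len": len(ann.utr5),
            "cds_len": len(ann.cds),
            "utr3_len": len(ann.utr3),
            "n_utis": count_utis(ann),
            "n_utis_canonical": count_utis(ann, canonical_filter="canonical"),
            "n_utis_noncanonical": count_utis(ann, canonical_filter="noncanonical"),
            "n_uorfs": len(detect_uorfs(ann)),
            **flags,
        }
        for d in distance_grid:
            row[f"n_utis_within_{d}"] = count_utis(ann, max_distance=d)
        rows[tid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    return df


def ingest_feature_table(path, gene_universe) -> pd.DataFrame:
    """Join an external per-gene numeric feature TSV onto the modelled genes.

    The first column must be the gene ID.  Unmatched genes get missing
    values; duplicate gene rows and non-numeric cells are errors.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    gene_col = raw.columns[0]
    dup = raw[gene_col][raw[gene_col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene row {dup.iloc[0]!r} in {path}")
    raw = raw.set_index(gene_col)
    for col in raw.columns:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = raw[col].notna() & parsed.isna()
        if bad.any():
            line = int(np.argmax(bad.values)) + 2  # header + 1-based
            raise ValueError(f"non-numeric value in column {col!r} at line {line} of {path}")
        raw[col] = parsed
    universe = list(gene_universe)
    if not set(universe) & set(raw.index):
        raise ValueError(f"no overlapping gene IDs between {path} and the model universe")
    out = raw.reindex(universe)
    out.index.name = "gene"
    logger.info("ingest_feature_table: %s -> %d/%d genes covered", path, out.notna().any(axis=1).sum(), len(universe))
    return out


# -- annotation I/O ---------------------------------------------------------


def write_annotations(annotations: dict, fasta_path, utis_path) -> None:
    """Write UTR/CDS sequences (FASTA, RNA alphabet) and the uTIS table (TSV).

    FASTA record IDs are ``<transcript>|5UTR`` / ``|CDS`` / ``|3UTR``; the
    uTIS table has columns transcript, offset (0-based within the 5'UTR),
    codon, canonical.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for tid in sorted(annotations):
        ann = annotations[tid]
        for region, seq in (("5UTR", ann.utr5), ("CDS", ann.cds), ("3UTR", ann.utr3)):
            records.append(SeqRecord(Seq(seq), id=f"{tid}|{region}", description=""))
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        (tid, u.offset, u.codon, int(u.canonical))
        for tid in sorted(annotations)
        for u in annotations[tid].utis_list
    ]
    pd.DataFrame(rows, columns=["transcript", "offset", "codon", "canonical"]).to_csv(
        utis_path, sep="\t", index=False
    )


def read_annotations(fasta_path, utis_path=None) -> dict:
    """Read TranscriptAnnotations back from FASTA + optional uTIS TSV.

    DNA input (T) is transliterated to U with a logged notice.
    """
    from Bio import SeqIO

    parts: dict[str, dict[str, str]] = {}
    saw_t = False
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tid, _, region = rec.id.partition("|")
        seq = str(rec.seq).upper()
        if "T" in seq:
            saw_t = True
            seq = seq.replace("T", "U")
        parts.setdefault(tid, {})[region] = seq
    if saw_t:
        logger.info("read_annotations: DNA alphabet detected, transliterated T -> U")
    utis_by_tid: dict[str, list[UTIS]] = {}
    if utis_path is not None:
        tab = pd.read_csv(utis_path, sep="\t")
        for _, row in tab.iterrows():
            utis_by_tid.setdefault(str(row["transcript"]), []).append(
                UTIS(int(row["offset"]), str(row["codon"]), bool(row["canonical"]))
            )
    out = {}
    for tid, regions in parts.items():
        out[tid] = TranscriptAnnotation(
            transcript_id=tid,
            utr5=regions.get("5UTR", ""),
            cds=regions.get("CDS", ""),
            utr3=regions.get("3UTR", ""),
            utis_list=utis_by_tid.get(tid, []),
        )
    return out


# -- association statistics -------------------------------------------------


def assoc_spearman(feature, improvements, min_pairs: int = 10):
    """Spearman rank correlation (average ranks for ties), two-sided p.

    Returns ``(rho, p)``; (nan, nan) with a log notice for constant input.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(improvements, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_pairs:
        raise ValueError(f"need >= {min_pairs} complete pairs, got {int(ok.sum())}")
    if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        logger.warning("assoc_spearman: constant input, correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def distance_profile(annotations: dict, improvements: pd.Series, distance_grid) -> pd.DataFrame:
    """Spearman rho/p between improvement and cumulative uTIS counts per window.

    For each distance d in the grid, counts uTISs within (0, d] nt of the
    aTIS per gene and correlates the counts with the accuracy improvement.
    Windows where every gene has zero uTISs are flagged undefined.
    """
    genes = [g for g in improvements.index if g in annotations]
    imp = improvements.loc[genes].values.astype(float)
    rows = []
    for d in distance_grid:
        counts = np.array([count_utis(annotations[g], max_distance=d) for g in genes], dtype=float)
        if counts.sum() == 0:
            rows.append((d, float("nan"), float("nan"), 0, False))
            continue
        rho, p = assoc_spearman(counts, imp)
        rows.append((d, rho, p, int(counts.sum()), True))
    return pd.DataFrame(rows, columns=["distance", "rho", "p", "n_utis", "defined"])


def fisher_exact_2x2(a: int, b: int, c: int, d: int):
    """Two-sided Fisher exact p for the table [[a, b], [c, d]] plus sample OR.

    Two-sided p sums, over the hypergeometric support at fixed margins, the
    probabilities of all tables at most as probable as the observed one (the
    conventional exact definition).  The sample odds ratio ad/bc is inf when
    only bc is zero and nan for degenerate margins.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        raise ValueError("empty table")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    p = min(p, 1.0)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, p


def assoc_fisher(informative_genes, feature_genes, universe):
    """Fisher's exact test of feature enrichment among informative genes.

    Builds the 2x2 table (informative x feature) over ``universe`` and
    returns ``(odds_ratio, p_two_sided, p_enrichment, table)`` where the
    one-sided enrichment p is the hypergeometric upper tail.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    inf_set = set(informative_genes) & universe
    feat_set = set(feature_genes) & universe
    a = len(inf_set & feat_set)
    b = len(inf_set - feat_set)
    c = len(feat_set - inf_set)
    d = len(universe - inf_set - feat_set)
    odds, p2 = fisher_exact_2x2(a, b, c, d)
    n = len(universe)
    p_enrich = float(stats.hypergeom.sf(a - 1, n, len(feat_set), len(inf_set)))
    if len(feat_set) == n or len(inf_set) == n or not feat_set or not inf_set:
        logger.warning("assoc_fisher: degenerate margin, odds ratio not interpretable")
    return odds, p2, p_enrich, ((a, b), (c, d))


def set_enrichment(gene_set, annotation_map: dict, universe) -> pd.DataFrame:
    """Hypergeometric over/under-representation of categories in ``gene_set``.

    ``annotation_map`` maps category -> iterable of genes (GO-slim style).
    Categories with no member in the universe are skipped.  The reported p
    is one-sided in the observed direction (enrichment when observed >=
    expected, depletion otherwise); BH adjustment across categories.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set) & universe
    n, N = len(gene_set), len(universe)
    rows = []
    for cat in sorted(annotation_map):
        members = set(annotation_map[cat]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(gene_set & members)
        expected = n * K / N
        fold = (k / expected) if expected > 0 else float("nan")
        if k >= expected:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            direction = "enriched"
        else:
            p = float(stats.hypergeom.cdf(k, N, K, n))
            direction = "depleted"
        rows.append((cat, k, K, fold, direction, p))
    df = pd.DataFrame(
        rows, columns=["category", "observed", "category_size", "fold", "direction", "p"]
    )
    df["p_adj"] = bh_adjust(df["p"].values) if len(df) else []
    return df
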