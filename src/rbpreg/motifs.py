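"""PWM scanning of UTR sequences and RBP-mRNA interaction inference.

Each RNA-binding protein is described by a position probability matrix over
{A, C, G, U} (RNAcompete / cisBP-RNA style).  Sequences are scanned on the
sense strand with log-odds scores against an i.i.d. background; per-score
p-values come from the exact null distribution computed by dynamic
programming on a discretized score grid (the FIMO construction).  Hits are
filtered by Benjamini-Hochberg q-value at a configurable FDR (20% by
default) and aggregated into a transcript -> RBP interaction map.

Coordinates are 0-based, half-open, within each UTR region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import logger

ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: score-grid resolution in bits; the null distribution and all reported
#: scores are exact multiples of this
SCORE_RESOLUTION = 1e-3


class SequenceAlphabetError(ValueError):
    """Raised when a scanned sequence contains a non-ACGU character."""


@dataclass
class MotifModel:
    """Position probability matrix for one RBP, with scanning parameters."""

    rbp_id: str
    matrix: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError(f"motif {self.rbp_id}: matrix must be width x 4, width >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.rbp_id}: position probabilities must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.rbp_id}: background must sum to 1")
        self._null_cache: tuple | None = None

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """width x 4 log2-odds matrix after pseudocount regularization."""
        m = self.matrix + self.pseudocount
        m = m / m.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):  # -inf at pseudocount 0, floored later
            return np.log2(m / self.background)

    def int_scores(self) -> np.ndarray:
        """Log-odds rounded onto the integer score grid (units of resolution).

        Zero-probability entries (possible at pseudocount 0) are floored at
        -64 bits per position so the grid stays finite; any word containing
        such a base scores far below every achievable match.
        """
        lo = np.maximum(self.log_odds(), -64.0)
        return np.rint(lo / SCORE_RESOLUTION).astype(np.int64)

    # -- exact null ---------------------------------------------------------

    def _null(self):
        """(offset, tail) of the exact null: tail[i] = P(score >= (i+offset)*res)."""
        if self._null_cache is not None:
            return self._null_cache
        ints = self.int_scores()
        lo = int(ints.min(axis=1).sum())
        hi = int(ints.max(axis=1).sum())
        span = hi - lo + 1
        if span > 50_000_000:
            raise ValueError(
                f"motif {self.rbp_id}: score grid spans {span} bins; "
                "use a coarser SCORE_RESOLUTION"
            )
        # DP convolution: start with a point mass, add one position at a time
        cur = np.array([1.0])
        cur_lo = 0
        for w in range(self.width):
            shifts = ints[w] - ints[w].min()
            width_new = len(cur) + int(shifts.max())
            nxt = np.zeros(width_new)
            for b in range(4):
                nxt[shifts[b] : shifts[b] + len(cur)] += cur * self.background[b]
            cur = nxt
            cur_lo += int(ints[w].min())
        assert cur_lo == lo and len(cur) == span
        total = cur.sum()
        if abs(total - 1.0) > 1e-6:
            raise AssertionError(f"null distribution mass {total} != 1")
        tail = np.cumsum(cur[::-1])[::-1]
        tail = np.minimum(tail, 1.0)
        self._null_cache = (lo, tail)
        return self._null_cache


def encode_sequence(seq: str) -> np.ndarray:
    """Map an RNA string to base indices, rejecting ambiguity codes."""
    idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
    out = table[idx]
    if (out < 0).any():
        pos = int(np.argmax(out < 0))
        raise SequenceAlphabetError(
            f"non-ACGU character {seq[pos]!r} at position {pos}"
        )
    return out.astype(np.int64)


def score_sequence(seq: str, motif: MotifModel) -> np.ndarray:
    """Log-odds score (bits) at every valid offset of ``seq``, sense strand.

    Scores are sums of grid-rounded per-position log-odds, so they live on
    the same grid as the exact null distribution.
    """
    idx = encode_sequence(seq)
    w = motif.width
    if len(idx) < w:
        raise ValueError(f"sequence length {len(idx)} < motif width {w}")
    ints = motif.int_scores()
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    scores = ints[np.arange(w)[None, :], windows].sum(axis=1)
    return scores * SCORE_RESOLUTION


def score_pvalue(score, motif: MotifModel):
    """P(null score >= observed) under the i.i.d. background, exact on the grid.

    Accepts a scalar or an array of scores.
    """
    lo, tail = motif._null()
    s = np.rint(np.asarray(score, dtype=float) / SCORE_RESOLUTION).astype(np.int64) - lo
    s = np.clip(s, 0, len(tail) - 1)
    p = tail[s]
    if np.ndim(score) == 0:
        return float(p)
    return p


# -- multiple testing -------------------------------------------------------


@dataclass
class MotifHit:
    rbp_id: str
    transcript_id: str
    region: str  # "5UTR" | "3UTR"
    start: int
    end: int
    score: float
    p_value: float
    q_value: float


@dataclass
class InteractionMap:
    """transcript -> {rbp_id: [retained MotifHit, ...]}."""

    targets: dict = field(default_factory=dict)

    def rbps_for(self, transcript_id: str) -> list[str]:
        return sorted(self.targets.get(transcript_id, {}))

    def transcripts(self) -> list[str]:
        return sorted(self.targets)

    @property
    def n_interactions(self) -> int:
        return sum(len(v) for v in self.targets.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, h.region, h.start, h.end, h.rbp_id, h.score, h.p_value, h.q_value)
            for t in sorted(self.targets)
            for r in sorted(self.targets[t])
            for h in self.targets[t][r]
        ]
        return pd.DataFrame(
            rows,
            columns=["transcript", "region", "start", "end", "rbp", "score", "p", "q"],
        )


def scan_and_filter(sequences, motifs, fdr: float = 0.20, scope: str = "pooled"):
    """Scan every UTR with every motif and retain hits at the given FDR.

    Parameters
    ----------
    sequences : iterable of (transcript_id, region, seq)
        ``region`` is "5UTR" or "3UTR"; sequences shorter than a motif are
        skipped for that motif.
    motifs : list of MotifModel
    fdr : float in (0, 1)
        Benjamini-Hochberg q-value cutoff (paper default 0.20).
    scope : {"pooled", "per_region"}
        Multiple-testing family per motif: all scanned positions of both UTR
        regions pooled (default, FIMO-like), or each region separately.

    Returns ``(InteractionMap, hits_frame)`` where the frame lists the
    retained hits.
    """
    if not motifs:
        raise ValueError("empty motif set")
    if not 0 < fdr < 1:
        raise ValueError(f"fdr must be in (0,1), got {fdr}")
    if scope not in ("pooled", "per_region"):
        raise ValueError(f"unknown q-value scope {scope!r}")
    from .signif import bh_adjust

    seqs = list(sequences)
    records = []
    for motif in motifs:
        per_family: dict[str, list] = {}
        for transcript_id, region, seq in seqs:
            if len(seq) < motif.width:
                continue
            scores = score_sequence(seq, motif)
            pvals = score_pvalue(scores, motif)
            fam = "all" if scope == "pooled" else region
            per_family.setdefault(fam, []).append(
                (transcript_id, region, scores, pvals)
            )
        for fam, chunks in per_family.items():
            pall = np.concatenate([c[3] for c in chunks])
            qall = bh_adjust(pall)
            ofs = 0
            for transcript_id, region, scores, pvals in chunks:
                q = qall[ofs : ofs + len(pvals)]
                ofs += len(pvals)
                keep = np.flatnonzero(q <= fdr)
                for i in keep:
                    records.append(
                        MotifHit(
                            rbp_id=motif.rbp_id,
                            transcript_id=transcript_id,
                            region=region,
                            start=int(i),
                            end=int(i) + motif.width,
                            score=float(scores[i]),
                            p_value=float(pvals[i]),
                            q_value=float(q[i]),
                        )
                    )
    imap = InteractionMap()
    for h in records:
        imap.targets.setdefault(h.transcript_id, {}).setdefault(h.rbp_id, []).append(h)
    frame = pd.DataFrame(
        [
            (h.transcript_id, h.region, h.start, h.end, h.rbp_id, h.score, h.p_value, h.q_value)
            for h in records
        ],
        columns=["transcript", "region", "start", "end", "rbp", "score", "p", "q"],
    ).sort_values(["transcript", "rbp", "region", "start"], kind="mergesort").reset_index(drop=True)
    logger.info(
        "scan_and_filter: %d retained hits, %d transcripts, fdr=%.2f",
        len(records), len(imap.targets), fdr,
    )
    return imap, frame


def restrict_to_measured(imap: InteractionMap, panel) -> InteractionMap:
    """Drop RBPs not measured at both the transcript and the protein level.

    Transcripts left without any RBP are removed from the map.
    """
    measured = set(panel.mrna.columns) & set(panel.protein.columns)
    out = InteractionMap()
    for t, rbps in imap.targets.items():
        kept = {r: list(hits) for r, hits in rbps.items() if r in measured}
        if kept:
            out.targets[t] = kept
    if not out.targets:
        logger.warning("restrict_to_measured: no interactions left after restriction")
    return out


# -- MEME minimal motif format ----------------------------------------------
# Hand-rolled because the available MEME parsers quantize letter
# probabilities into integer counts, which breaks exact-null arithmetic.


def write_meme(motifs: list[MotifModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.rbp_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[MotifModel]:
    """Parse a minimal MEME motif file over the ACGU (or ACGT) alphabet."""
    motifs_out: list[MotifModel] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[j].replace("T", "U"): float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq[b] for b in ALPHABET])
        elif ln.startswith("MOTIF"):
            rbp_id = ln.split()[1]
            i += 1
            while not lines[i].startswith("letter-probability matrix"):
                i += 1
            header = lines[i]
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(w):
                i += 1
                rows.append([float(v) for v in lines[i].split()])
            matrix = np.array(rows)
            matrix = matrix / matrix.sum(axis=1, keepdims=True)  # guard rounding
            motifs_out.append(MotifModel(rbp_id=rbp_id, matrix=matrix, background=background))
        i += 1
    return motifs_out
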