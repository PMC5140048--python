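"""Synthetic matched panels, motif compendia, UTR sequences and uTIS tables.

The generator emulates the statistical structure the analysis assumes, with
full ground truth:

* protein abundance follows the linear generative law
  ``PROT_ij = b0_j + bm_j * mRNA_ij + sum_k bR_jk * RBP_ik + eps_ij`` with
  Gaussian noise, on the log scale, with mRNA and RBP protein levels drawn
  standard normal (panels are mean-centred downstream in any case);
* a configurable fraction of genes is "regulated" (nonzero RBP
  coefficients); the rest have all bR_jk = 0;
* every true (RBP, gene) interaction is backed by the RBP's motif consensus
  planted at a recorded position in the gene's UTRs;
* upstream TISs (canonical AUG and near-cognate starts) are planted with a
  configurable enrichment odds ratio in regulated versus unregulated genes;
* missing entries are injected completely at random.

UTR backgrounds are i.i.d. uniform over {A, C, G, U}, which matches the
scanner's exact null.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import UTIS, TranscriptAnnotation, detect_uorfs, write_annotations
from .motifs import ALPHABET, MotifModel, write_meme
from .panels import ExpressionPanel
from .util import logger, stable_seed

NEAR_COGNATE_PLANTED = ("CUG", "GUG", "ACG")
_NON_STOP_CODONS = [
    a + b + c
    for a in ALPHABET for b in ALPHABET for c in ALPHABET
    if a + b + c not in ("UAA", "UAG", "UGA")
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic panel.

    The defaults are the conditions the package's tests and the acceptance
    pipeline run under: 60 samples (between the 12-tissue and 87-sample real
    panels), 200 genes, 20 RBPs, 30% regulated genes whose RBP terms carry
    a large share of protein variance, unit residual noise on the log scale,
    and a threefold uTIS enrichment odds in regulated genes.
    """

    n_samples: int = 60
    n_genes: int = 200
    n_rbps: int = 20
    frac_regulated: float = 0.3
    beta_mrna_range: tuple = (0.5, 1.5)
    rbp_effect_sd: float = 1.0
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    utr5_length_range: tuple = (80, 200)
    motif_width: int = 8
    utis_enrichment_odds: float = 3.0
    seed: int = 0
    # secondary knobs (held fixed across the test suite)
    utr3_length_range: tuple = (80, 200)
    cds_length_range: tuple = (60, 180)
    rbps_per_gene_range: tuple = (2, 5)
    sites_per_interaction: int = 1
    site_3utr_fraction: float = 0.5
    utis_base_rate: float = 0.35
    utis_mean_extra: float = 0.7
    canonical_utis_fraction: float = 0.6
    utis_min_distance: int = 0
    rbp_mrna_noise_sd: float = 0.5
    beta0_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("frac_regulated", "missing_rate", "site_3utr_fraction",
                     "canonical_utis_fraction", "utis_base_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        if self.n_samples < 6:
            raise ConfigurationError(
                f"n_samples={self.n_samples} < 6: cannot run 5-fold outer CV"
            )
        if self.motif_width < 4:
            raise ConfigurationError(f"motif_width={self.motif_width} must be >= 4")
        if self.utis_enrichment_odds <= 0:
            raise ConfigurationError("utis_enrichment_odds must be > 0")
        if self.noise_sd < 0 or self.rbp_effect_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic panel."""

    gene_ids: list
    rbp_ids: list
    beta0: pd.Series
    beta_mrna: pd.Series
    beta_rbp: pd.DataFrame  # genes x rbps, exact zeros off the support
    regulated: pd.Series
    planted_sites: dict = field(default_factory=dict)  # gene -> [site dict]
    utis: dict = field(default_factory=dict)  # gene -> [(offset, codon, canonical)]
    uorfs: dict = field(default_factory=dict)  # gene -> [(start, stop_end, class)]

    def rbps_of(self, gene: str) -> list:
        row = self.beta_rbp.loc[gene]
        return list(row.index[row != 0])


def _make_truth(config: SimConfig) -> SyntheticTruth:
    rng = np.random.default_rng(stable_seed(config.seed, "truth"))
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    rbps = [f"RBP{i + 1:02d}" for i in range(config.n_rbps)]
    n_reg = int(round(config.frac_regulated * config.n_genes))
    if config.frac_regulated > 0 and n_reg < 1:
        warnings.warn("frac_regulated * n_genes < 1: zero regulated genes")
        n_reg = 0
    reg_idx = rng.choice(config.n_genes, size=n_reg, replace=False)
    regulated = np.zeros(config.n_genes, dtype=bool)
    regulated[reg_idx] = True
    beta0 = rng.normal(0.0, config.beta0_sd, config.n_genes)
    lo, hi = config.beta_mrna_range
    beta_mrna = rng.uniform(lo, hi, config.n_genes)
    beta_rbp = np.zeros((config.n_genes, config.n_rbps))
    klo, khi = config.rbps_per_gene_range
    for j in np.flatnonzero(regulated):
        k = int(rng.integers(klo, min(khi, config.n_rbps) + 1))
        cols = rng.choice(config.n_rbps, size=k, replace=False)
        beta_rbp[j, cols] = rng.normal(0.0, config.rbp_effect_sd, k)
    return SyntheticTruth(
        gene_ids=genes,
        rbp_ids=rbps,
        beta0=pd.Series(beta0, index=genes),
        beta_mrna=pd.Series(beta_mrna, index=genes),
        beta_rbp=pd.DataFrame(beta_rbp, index=genes, columns=rbps),
        regulated=pd.Series(regulated, index=genes),
    )


def generate_panel(config: SimConfig, truth: SyntheticTruth | None = None,
                   noise_seed: int | None = None):
    """Draw one matched mRNA/protein panel under the linear generative law.

    Passing an existing ``truth`` together with a different ``noise_seed``
    regenerates an independent panel over the same ground truth (used for
    cross-panel transfer).  Identical config and seeds give bit-identical
    output.

    Returns ``(ExpressionPanel, SyntheticTruth)``.
    """
    if truth is None:
        truth = _make_truth(config)
    rng = np.random.default_rng(
        stable_seed(config.seed if noise_seed is None else noise_seed, "panel")
    )
    n, G, K = config.n_samples, config.n_genes, config.n_rbps
    samples = [f"S{i + 1:03d}" for i in range(n)]
    mrna_genes = rng.normal(0.0, 1.0, (n, G))
    rbp_protein = rng.normal(0.0, 1.0, (n, K))
    rbp_mrna = rbp_protein + rng.normal(0.0, config.rbp_mrna_noise_sd, (n, K))
    eps = rng.normal(0.0, config.noise_sd, (n, G)) if config.noise_sd > 0 else np.zeros((n, G))
    protein_genes = (
        truth.beta0.values[None, :]
        + truth.beta_mrna.values[None, :] * mrna_genes
        + rbp_protein @ truth.beta_rbp.values.T
        + eps
    )
    mrna = pd.DataFrame(
        np.hstack([mrna_genes, rbp_mrna]), index=samples,
        columns=truth.gene_ids + truth.rbp_ids,
    )
    protein = pd.DataFrame(
        np.hstack([protein_genes, rbp_protein]), index=samples,
        columns=truth.gene_ids + truth.rbp_ids,
    )
    if config.missing_rate > 0:
        for df in (mrna, protein):
            mask = rng.random(df.shape) < config.missing_rate
            df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns), inplace=True)
    mrna.index.name = protein.index.name = "sample"
    return ExpressionPanel(mrna, protein, meta="synthetic"), truth


def generate_motifs(config: SimConfig, seed: int | None = None) -> list[MotifModel]:
    """One sharp PWM per synthetic RBP: 0.97 on a random consensus base."""
    rng = np.random.default_rng(stable_seed(config.seed if seed is None else seed, "motifs"))
    out = []
    for i in range(config.n_rbps):
        cons = rng.integers(0, 4, config.motif_width)
        m = np.full((config.motif_width, 4), 0.01)
        m[np.arange(config.motif_width), cons] = 0.97
        out.append(MotifModel(rbp_id=f"RBP{i + 1:02d}", matrix=m))
    return out


def _random_seq(rng, length: int) -> list:
    return list(rng.choice(list(ALPHABET), size=length))


def _allocate(rng, occupied: list, length: int, span: int, lo: int = 0, hi: int | None = None):
    """Place an interval of ``span`` nt avoiding ``occupied``; None if stuck."""
    hi = length if hi is None else hi
    if hi - lo < span:
        return None
    for _ in range(60):
        s = int(rng.integers(lo, hi - span + 1))
        if all(s + span <= a or s >= b for a, b in occupied):
            occupied.append((s, s + span))
            return s
    return None


def _gene_sequence(rng, config: SimConfig, gene: str, truth: SyntheticTruth,
                   consensus: dict, utis_plan: list):
    """Assemble one transcript; returns (annotation, sites).  Retries with
    longer UTRs when the planting plan does not fit (logged)."""
    site_plan = []
    for rbp in truth.rbps_of(gene):
        for _ in range(config.sites_per_interaction):
            region = "3UTR" if rng.random() < config.site_3utr_fraction else "5UTR"
            site_plan.append((rbp, region))
    l5 = int(rng.integers(config.utr5_length_range[0], config.utr5_length_range[1] + 1))
    l3 = int(rng.integers(config.utr3_length_range[0], config.utr3_length_range[1] + 1))
    for attempt in range(8):
        occ5: list = []
        occ3: list = []
        sites = []
        ok = True
        for rbp, region in site_plan:
            w = len(consensus[rbp])
            length, occ = (l5, occ5) if region == "5UTR" else (l3, occ3)
            s = _allocate(rng, occ, length, w)
            if s is None:
                ok = False
                break
            sites.append({"rbp": rbp, "region": region, "start": s, "end": s + w})
        utis_placed = []
        if ok:
            for codon, canonical in utis_plan:
                hi = l5 - max(3, config.utis_min_distance)
                s = _allocate(rng, occ5, l5, 3, lo=0, hi=max(hi + 3, 0))
                if s is None or l5 - s < config.utis_min_distance:
                    ok = False
                    break
                utis_placed.append(UTIS(s, codon, canonical))
        if ok:
            seq5 = _random_seq(rng, l5)
            seq3 = _random_seq(rng, l3)
            for site in sites:
                target = seq5 if site["region"] == "5UTR" else seq3
                target[site["start"]:site["end"]] = list(consensus[site["rbp"]])
            for u in utis_placed:
                seq5[u.offset:u.offset + 3] = list(u.codon)
            clo, chi = config.cds_length_range
            n_codons = max(3, int(rng.integers(clo, chi + 1)) // 3)
            cds = "AUG" + "".join(rng.choice(_NON_STOP_CODONS, size=n_codons - 2)) + "UAA"
            ann = TranscriptAnnotation(
                transcript_id=gene, utr5="".join(seq5), cds=cds, utr3="".join(seq3),
                utis_list=sorted(utis_placed, key=lambda u: u.offset),
            )
            return ann, sites
        l5 = int(l5 * 1.5) + 10
        l3 = int(l3 * 1.5) + 10
        logger.info("gene %s: planting plan did not fit, retrying with longer UTRs (%d/%d)", gene, l5, l3)
    raise RuntimeError(f"gene {gene}: could not place planted elements")


def generate_sequences(config: SimConfig, truth: SyntheticTruth,
                       pwms: list[MotifModel] | None = None,
                       seed: int | None = None):
    """Generate UTR/CDS sequences with planted motif sites and uTISs.

    Every nonzero beta_RBP interaction gets its RBP's consensus planted at a
    recorded position (0-based half-open); uTIS codons are planted so that
    regulated genes carry them at the configured enrichment odds.  Returns
    ``(annotations, ledger)`` where the ledger records all planted
    coordinates and the uORFs derived from the planted uTISs.
    """
    if pwms is None:
        pwms = generate_motifs(config, seed=seed)
    if len(pwms) != config.n_rbps:
        raise ValueError("need exactly one PWM per synthetic RBP")
    consensus = {m.rbp_id: m.consensus for m in pwms}
    rng = np.random.default_rng(
        stable_seed(config.seed if seed is None else seed, "sequences")
    )
    p0 = config.utis_base_rate
    odds0 = p0 / (1 - p0) if p0 < 1 else float("inf")
    odds1 = odds0 * config.utis_enrichment_odds
    p1 = odds1 / (1 + odds1)
    annotations = {}
    for gene in truth.gene_ids:
        p_utis = p1 if truth.regulated[gene] else p0
        n_utis = 0
        if rng.random() < p_utis:
            n_utis = 1 + int(rng.poisson(config.utis_mean_extra))
        plan = []
        for _ in range(n_utis):
            if rng.random() < config.canonical_utis_fraction:
                plan.append(("AUG", True))
            else:
                plan.append((str(rng.choice(NEAR_COGNATE_PLANTED)), False))
        ann, sites = _gene_sequence(rng, config, gene, truth, consensus, plan)
        annotations[gene] = ann
        truth.planted_sites[gene] = sites
        truth.utis[gene] = [(u.offset, u.codon, u.canonical) for u in ann.utis_list]
        truth.uorfs[gene] = [
            (o.start, o.stop_end, o.frame_class) for o in detect_uorfs(ann)
        ]
    ledger = {
        gene: {
            "regulated": bool(truth.regulated[gene]),
            "beta0": float(truth.beta0[gene]),
            "beta_mrna": float(truth.beta_mrna[gene]),
            "beta_rbp": {r: float(truth.beta_rbp.loc[gene, r]) for r in truth.rbps_of(gene)},
            "sites": truth.planted_sites[gene],
            "utis": [
                {"offset": o, "codon": c, "canonical": bool(f)}
                for o, c, f in truth.utis[gene]
            ],
            "uorfs": [
                {"start": s, "stop_end": e, "frame_class": fc}
                for s, e, fc in truth.uorfs[gene]
            ],
        }
        for gene in truth.gene_ids
    }
    return annotations, ledger


# -- fixture suite ----------------------------------------------------------

FIXTURE_CONFIG = SimConfig(n_samples=20, n_genes=80, n_rbps=10, noise_sd=1.0)


def write_panel(panel: ExpressionPanel, mrna_path, protein_path) -> None:
    panel.mrna.to_csv(mrna_path, sep="\t", na_rep="", float_format="%.10g")
    panel.protein.to_csv(protein_path, sep="\t", na_rep="", float_format="%.10g")


def make_fixture_suite(out_dir, seed: int = 0, config: SimConfig | None = None) -> dict:
    """Write a small synthetic dataset in the external-interface formats.

    Produces ``mrna.tsv``, ``protein.tsv``, ``motifs.meme``, ``utrs.fa``,
    ``utis.tsv`` and ``truth.json`` under ``out_dir`` and returns the paths.
    The files parse back into objects equal to the in-memory ones.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = replace(FIXTURE_CONFIG, seed=seed)
    panel, truth = generate_panel(config)
    pwms = generate_motifs(config)
    annotations, ledger = generate_sequences(config, truth, pwms)
    paths = {
        "mrna": out / "mrna.tsv",
        "protein": out / "protein.tsv",
        "motifs": out / "motifs.meme",
        "fasta": out / "utrs.fa",
        "utis": out / "utis.tsv",
        "truth": out / "truth.json",
    }
    write_panel(panel, paths["mrna"], paths["protein"])
    write_meme(pwms, paths["motifs"])
    write_annotations(annotations, paths["fasta"], paths["utis"])
    with open(paths["truth"], "w") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
    logger.info("make_fixture_suite: wrote %d genes x %d samples to %s",
                config.n_genes, config.n_samples, out)
    return {k: str(v) for k, v in paths.items()}
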