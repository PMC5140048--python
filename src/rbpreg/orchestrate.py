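"""End-to-end pipeline driver: configuration, seeding, staging, manifest.

Runs the stages in method order -- simulate/load, filter+centre, scan,
fit, randomization test, feature association, RBP prioritization, optional
cross-panel transfer -- writing every stage artifact as TSV/JSON into a run
directory and hashing each file into a manifest.  Identical config and
master seed give byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import downstream, features, models, motifs, panels, signif, synthdata
from .util import logger, stable_seed


class StageError(RuntimeError):
    """A pipeline stage failed or a required upstream artifact is missing."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Threshold defaults: detection filter 3 missing samples (<=12-sample
    panels) else 5, motif FDR 20%, 5-fold outer and inner CV, 1000
    randomizations, informative call at raw p < 0.05, distance grid up to
    400 nt.
    """

    out_dir: str = "run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    do_filter: bool = True
    do_scan: bool = True
    do_fit: bool = True
    do_test: bool = True
    do_associate: bool = True
    do_prioritize: bool = True
    do_transfer: bool = False
    # inputs when simulate=False
    mrna_path: str | None = None
    protein_path: str | None = None
    motifs_path: str | None = None
    fasta_path: str | None = None
    utis_path: str | None = None
    # stage parameters
    sim: dict = field(default_factory=dict)  # overrides for SimConfig
    max_missing: int | None = None
    fdr: float = 0.20
    qvalue_scope: str = "pooled"
    penalty: str = "ridge"
    k_folds: int = 5
    inner_k: int = 5
    n_perm: int = 1000
    scheme: str = "by_rbp"
    alpha_informative: float = 0.05
    distance_grid: tuple = (50, 100, 150, 200, 250, 300, 350, 400)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path, include_out_dir: bool = True) -> None:
        data = dataclasses.asdict(self)
        if not include_out_dir:
            # the resolved copy inside a run directory must not depend on
            # where that directory lives, or manifests lose determinism
            data.pop("out_dir")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    Every stage output is written under ``config.out_dir`` and hashed into
    ``manifest.json``.  A stage failure aborts with the stage name; the
    partial manifest is still written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "files": {}}
    config.to_yaml(out / "config.yaml", include_out_dir=False)
    manifest["files"]["config.yaml"] = _sha256(out / "config.yaml")

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["files"][name] = _sha256(path)
        return path

    def finish_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    stage = "setup"
    try:
        # -- simulate / load ------------------------------------------------
        stage = "simulate"
        truth = None
        if config.simulate:
            sim_cfg = dataclasses.replace(
                synthdata.SimConfig(), seed=config.seed, **config.sim
            )
            panel, truth = synthdata.generate_panel(sim_cfg)
            pwms = synthdata.generate_motifs(sim_cfg)
            annotations, ledger = synthdata.generate_sequences(sim_cfg, truth, pwms)
            emit("mrna.tsv", lambda p: synthdata.write_panel(panel, p, out / "protein.tsv"))
            manifest["files"]["protein.tsv"] = _sha256(out / "protein.tsv")
            emit("motifs.meme", lambda p: motifs.write_meme(pwms, p))
            emit("utrs.fa", lambda p: features.write_annotations(annotations, p, out / "utis.tsv"))
            manifest["files"]["utis.tsv"] = _sha256(out / "utis.tsv")
            emit("truth.json", lambda p: json.dump(ledger, open(p, "w"), indent=1, sort_keys=True))
        else:
            stage = "load"
            if not (config.mrna_path and config.protein_path):
                raise StageError("load: mrna_path and protein_path required when simulate=False")
            panel = panels.load_panel(config.mrna_path, config.protein_path)
            pwms = motifs.read_meme(config.motifs_path) if config.motifs_path else []
            annotations = (
                features.read_annotations(config.fasta_path, config.utis_path)
                if config.fasta_path else {}
            )

        # -- filter / centre ------------------------------------------------
        if config.do_filter:
            stage = "filter"
            panel, retained, excluded = panels.filter_detected(panel, config.max_missing)
            emit("retained_genes.tsv", lambda p: pd.DataFrame({"gene": retained}).to_csv(p, sep="\t", index=False))
            panel = panels.mean_center(panel)
            emit("panel_centered_mrna.tsv", lambda p: synthdata.write_panel(panel, p, out / "panel_centered_protein.tsv"))
            manifest["files"]["panel_centered_protein.tsv"] = _sha256(out / "panel_centered_protein.tsv")

        # -- scan -----------------------------------------------------------
        if config.do_scan:
            stage = "scan"
            seq_iter = [
                (tid, region, seq)
                for tid, ann in sorted(annotations.items())
                for region, seq in (("5UTR", ann.utr5), ("3UTR", ann.utr3))
            ]
            imap, hit_frame = motifs.scan_and_filter(
                seq_iter, pwms, fdr=config.fdr, scope=config.qvalue_scope
            )
            imap = motifs.restrict_to_measured(imap, panel)
            emit("hits.tsv", lambda p: _write_tsv(hit_frame, p))

        # -- fit ------------------------------------------------------------
        if config.do_fit:
            stage = "fit"
            if not config.do_scan:
                raise StageError("fit: requires the scan stage (interaction map)")
            pairs, fits = models.fit_panel(
                panel, imap, penalty=config.penalty, seed=config.seed,
                k=config.k_folds, inner_k=config.inner_k,
            )
            emit("accuracy.tsv", lambda p: _write_tsv(pairs, p))

        # -- randomization test ---------------------------------------------
        if config.do_test:
            stage = "test"
            if not config.do_fit:
                raise StageError("test: requires the fit stage (accuracy table)")
            nulls = {}
            for gene in pairs["gene"]:
                nulls[gene] = signif.test_gene(
                    panel, imap, gene, config.scheme,
                    n_perm=config.n_perm, seed=config.seed,
                    penalty="ridge", inner_k=config.inner_k, k=config.k_folds,
                )
            records = signif.significance_table(pairs, nulls)
            sig = signif.call_informative(pairs, records)
            emit("significance.tsv", lambda p: _write_tsv(sig, p))
            null_rows = pd.DataFrame(
                [
                    (g, nulls[g].scheme, i, nulls[g].null_r2[i])
                    for g in sorted(nulls)
                    for i in range(len(nulls[g].null_r2))
                ],
                columns=["gene", "scheme", "replicate", "r2"],
            )
            emit("null_r2.tsv", lambda p: _write_tsv(null_rows, p))
            w_stat, w_p, w_method = signif.compare_models_wilcoxon(pairs)
            manifest["wilcoxon"] = {"W": w_stat, "p": w_p, "method": w_method}

        # -- feature association --------------------------------------------
        if config.do_associate:
            stage = "associate"
            sig_path = out / "significance.tsv"
            if not sig_path.exists():
                raise StageError("associate: missing significance table (run the test stage)")
            sig = pd.read_csv(sig_path, sep="\t")
            feats = features.feature_table(
                {g: annotations[g] for g in sig["gene"] if g in annotations},
                distance_grid=config.distance_grid,
            )
            emit("features.tsv", lambda p: _write_tsv(feats.reset_index(), p))
            imp = sig.set_index("gene")["improvement"]
            assoc_rows = []
            for col in ["utr5_len", "cds_len", "utr3_len", "n_utis",
                        "n_utis_canonical", "n_uorfs"]:
                common = feats.index.intersection(imp.index)
                try:
                    rho, p = features.assoc_spearman(feats.loc[common, col], imp.loc[common])
                except ValueError:
                    rho, p = float("nan"), float("nan")
                assoc_rows.append((col, "spearman", rho, p, len(common)))
            assoc = pd.DataFrame(assoc_rows, columns=["feature", "statistic", "estimate", "p", "n"])
            assoc["p_adj"] = signif.bh_adjust(np.nan_to_num(assoc["p"].values, nan=1.0))
            emit("associations.tsv", lambda p: _write_tsv(assoc, p))
            informative = set(sig.loc[sig["informative"].astype(bool), "gene"])
            utis_genes = set(feats.index[feats["n_utis"] > 0])
            odds, p2, p_enr, table = features.assoc_fisher(informative, utis_genes, set(feats.index))
            profile = features.distance_profile(
                {g: annotations[g] for g in feats.index}, imp.loc[feats.index],
                config.distance_grid,
            )
            emit("distance_profile.tsv", lambda p: _write_tsv(profile, p))
            manifest["utis_fisher"] = {
                "odds_ratio": odds, "p_two_sided": p2, "p_enrichment": p_enr,
                "table": table, "n_informative": len(informative),
            }

        # -- prioritize ------------------------------------------------------
        if config.do_prioritize:
            stage = "prioritize"
            if not config.do_associate:
                raise StageError("prioritize: requires the associate stage")
            prio = downstream.prioritize_rbps(informative, imap, annotations)
            emit("priority.tsv", lambda p: _write_tsv(prio.table, p))
            manifest["priority"] = {
                "n_eligible": prio.n_eligible, "n_skipped": prio.n_skipped,
            }

        # -- transfer --------------------------------------------------------
        if config.do_transfer:
            stage = "transfer"
            if truth is None:
                raise StageError("transfer: only available for simulated runs")
            test_panel, _ = synthdata.generate_panel(
                sim_cfg, truth=truth, noise_seed=stable_seed(config.seed, "transfer-panel")
            )
            report = downstream.cross_panel_transfer(
                panel, imap, panels.mean_center(test_panel),
                penalty="ridge", inner_k=config.inner_k, seed=config.seed,
            )
            emit("transfer.tsv", lambda p: _write_tsv(report["accuracies"], p))
            manifest["transfer"] = {
                k: report[k] for k in
                ("rho", "p", "n_shared_genes", "n_shared_rbps", "n_transferred",
                 "n_fallback", "n_skipped")
            }
    except Exception:
        manifest["failed_stage"] = stage
        finish_manifest()
        logger.error("pipeline aborted in stage %r", stage)
        raise
    finish_manifest()
    return manifest


def summary_report(run_dir) -> str:
    """Human-readable run summary: counts, cohort test, top associations/RBPs."""
    run = Path(run_dir)
    lines = [f"run directory: {run}"]
    manifest_path = run / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"master seed: {manifest.get('seed')}")
        if "failed_stage" in manifest:
            lines.append(f"WARNING: run aborted in stage {manifest['failed_stage']!r}")
    else:
        lines.append("WARNING: no manifest found; partial report")
    acc_path = run / "accuracy.tsv"
    if acc_path.exists():
        acc = pd.read_csv(acc_path, sep="\t")
        lines.append(f"modeled genes: {len(acc)}")
        lines.append(f"median improvement (R2_RBP+ - R2_RNAonly): {acc['improvement'].median():.4f}")
    if "wilcoxon" in manifest:
        w = manifest["wilcoxon"]
        lines.append(f"cohort Wilcoxon signed-rank: W = {w['W']:.1f}, p = {w['p']:.3g} ({w['method']})")
    sig_path = run / "significance.tsv"
    if sig_path.exists():
        sig = pd.read_csv(sig_path, sep="\t")
        n_inf = int(sig["informative"].astype(bool).sum())
        lines.append(f"informative genes: {n_inf} / {len(sig)} "
                     f"({100.0 * n_inf / max(len(sig), 1):.1f}%)")
    else:
        lines.append("informative genes: 0 (test stage not run)")
    if "utis_fisher" in manifest:
        f = manifest["utis_fisher"]
        lines.append(
            f"uTIS enrichment among informative genes: OR = {f['odds_ratio']:.2f}, "
            f"two-sided p = {f['p_two_sided']:.3g}"
        )
    prio_path = run / "priority.tsv"
    if prio_path.exists():
        prio = pd.read_csv(prio_path, sep="\t")
        if len(prio):
            top = prio.iloc[0]
            lines.append(f"top-ranked RBP by uTIS proximity: {top['rbp']} "
                         f"({top['n_genes']} genes, {top['pct']:.1f}%)")
        else:
            lines.append("top-ranked RBP by uTIS proximity: none (no eligible genes)")
    if "transfer" in manifest:
        t = manifest["transfer"]
        lines.append(f"cross-panel transfer: rho = {t['rho']:.3f} over "
                     f"{t['n_transferred']} genes")
    return "\n".join(lines) + "\n"
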