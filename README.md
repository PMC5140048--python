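# rbpreg

Transcript levels predict protein levels imperfectly: a large share of the
discrepancy is post-transcriptional, and RNA-binding proteins (RBPs) acting
on mRNA untranslated regions are prime suspects. `rbpreg` quantifies how
much RBP–mRNA interactions improve prediction of protein abundance from
mRNA abundance in matched transcriptome/proteome panels (tissues or cell
lines profiled at both levels), and asks which transcript features — in
particular upstream translation initiation sites (uTISs) in 5'UTRs — mark
the genes where RBPs are informative. It is written for computational
biologists integrating proteogenomic panels, and ships a synthetic-data
generator with full ground truth so that every stage of the analysis is
testable end to end.

## The model

For each gene *j* with protein abundance `PROT_ij` and transcript abundance
`mRNA_ij` across samples *i* (log scale, per-sample mean-centred), two
models are compared:

- **RNA-only** (simple linear regression):

  `PROT_ij = β0_j + β_mRNA,j · mRNA_ij + ε_ij`

- **RBP-plus** (penalized multiple regression):

  `PROT_ij = β0_j + β_mRNA,j · mRNA_ij + Σ_k β_RBP,jk · RBP_ik + ε_ij`

where `RBP_ik` are the measured *protein* levels of the RBPs inferred to
bind gene *j*'s UTRs (PWM scanning with exact null p-values, hits retained
at Benjamini–Hochberg FDR 20%). The RBP block carries a ridge (or lasso)
penalty; the intercept and mRNA coefficient are exactly unpenalized, so
with uninformative RBPs the RBP-plus model collapses onto the RNA-only
model. Accuracy is the cross-validated `R² = 1 − Σ(y_i−f_i)²/Σ(y_i−⟨y⟩)²`
of held-out predictions under nested 5-fold CV (penalty tuned in inner
folds of the training split only), and the per-gene improvement is
`R²_RBP+ − R²_RNAonly`.

Significance is empirical: each gene's RBP-plus accuracy is compared with
randomized models refit by the identical nested-CV pipeline, either
substituting the RBPs with randomly drawn proteins (`by_rbp`) or permuting
the RBP block across samples (`by_sample`). A gene is *informative* when
its RBP-plus accuracy beats RNA-only and the `by_rbp` empirical p < 0.05;
Storey q-values are reported alongside. Downstream, the improvement is
tested for association with uTIS counts (Spearman, cumulative distance
windows), uTIS/uORF content (Fisher's exact test), and initiation-context
patterns (Kozak `GCCRCCAUGG`, −3R/+4G, the TIS motif `RYMRMVAUGGC`); RBPs
are prioritized by owning the binding site nearest to a uTIS, and model
transferability across panels is scored by Spearman correlation of test-
panel accuracies.

## Worked example

Run the whole pipeline on a synthetic panel (200 genes, 60 samples, 20
RBPs, 30% regulated genes, threefold uTIS enrichment odds in regulated
genes, 200 randomizations) and summarize it:

```sh
rbpreg run --config cfg.yaml     # cfg.yaml: {out_dir: run1, seed: 1, n_perm: 200, do_transfer: true}
rbpreg report --run-dir run1
```

```
run directory: run1
master seed: 1
modeled genes: 77
median improvement (R2_RBP+ - R2_RNAonly): 0.3937
cohort Wilcoxon signed-rank: W = 2728.0, p = 6.07e-12 (normal)
informative genes: 60 / 77 (77.9%)
uTIS enrichment among informative genes: OR = 4.99, two-sided p = 0.0142
top-ranked RBP by uTIS proximity: RBP02 (5 genes, 17.9%)
cross-panel transfer: rho = 0.974 over 77 genes
```

Reading this: 77 genes carried at least one retained RBP binding site and
were modelled both ways. Adding RBP protein levels raised the median
held-out R² by 0.39 (cohort-level Wilcoxon signed-rank p ≈ 6·10⁻¹²), and
for 60 genes the gain beat random protein predictors (informative genes;
on this synthetic panel those are overwhelmingly the truly regulated
genes). uTIS-containing genes are strongly over-represented among the
informative genes (odds ratio 4.99, Fisher p = 0.014), mirroring the
planted enrichment, and models trained on one panel rank genes on an
independently re-drawn panel almost identically (ρ = 0.97).

Individual stages are also available: `rbpreg simulate`, `rbpreg panel
filter|center|diagnose`, `rbpreg scan`, or programmatically via
`rbpreg.generate_panel`, `rbpreg.scan_and_filter`, `rbpreg.fit_panel`,
`rbpreg.randomize_by_rbp`, `rbpreg.assoc_fisher`, and friends.

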