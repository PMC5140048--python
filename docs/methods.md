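# Methods

## Data model and preprocessing

A panel is a pair of samples × genes matrices of log-scale abundance —
transcripts (e.g. log10 FPKM or microarray intensity) and proteins (e.g.
log10 iBAQ or spectral counts) — over a shared sample set. Values below
the detection limit arrive as zeros or empty cells and are stored as
missing; nothing is imputed, and every statistic downstream is computed
over observed entries only.

Two preprocessing steps precede modelling:

1. **Detection filter.** A gene is kept only if its undetected-sample
   count is at most `max_missing` at *both* the mRNA and the protein
   level. The default is 3 for panels of ≤ 12 samples and 5 otherwise,
   matching the filtering regimes appropriate to small tissue panels
   versus larger cell-line/tumour panels; both are overridable.
2. **Per-sample mean-centring.** Each sample row of each matrix is
   centred to mean 0 over its observed entries. This removes global
   per-sample shifts so that average abundance cannot masquerade as
   predictive signal. Centring is applied after filtering (the order
   matters and is fixed); it is idempotent and preserves all within-sample
   differences exactly.

Cook's distances for each gene's simple protein ~ mRNA regression are
available as a per-sample influence diagnostic (reported, never used to
drop data). Genes with fewer than 4 complete observations are flagged
undefined.

## RBP–mRNA interaction inference

Each RBP's sequence preference is a position probability matrix over
{A,C,G,U}. Scanning is sense-strand log-odds: a pseudocount (default 0.01)
is added to matrix entries and rows renormalized, scores are
`Σ_w log2(p_w,b / bg_b)` in bits, computed on a discretized grid
(resolution 1e−3 bits). The p-value of a score is the exact tail
probability of the null score distribution under an i.i.d. background,
obtained by dynamic-programming convolution of the per-position score
distributions on the same grid — so p-values agree exactly (at grid
resolution) with brute-force enumeration over all 4^w words, which the
test suite verifies for every width ≤ 6. Backgrounds default to uniform;
zero-probability entries (possible at pseudocount 0) are floored at −64
bits per position to keep the grid finite.

Per motif, all scanned positions of all sequences form one
Benjamini–Hochberg family (5' and 3' UTR positions pooled by default,
per-region scope available); hits with q ≤ FDR (default 20%) are retained
and aggregated into a transcript → RBP interaction map. The map is then
restricted to RBPs measured at both the transcript and protein level in
the panel at hand. Overlapping hits of one motif are all kept — downstream
stages need the RBP set and site coordinates, not a segmentation.

DNA-alphabet FASTA input is transliterated T→U with a logged notice;
ambiguity codes are rejected rather than scanned.

## Per-gene dual models under nested CV

For each mapped gene, samples with any missing value among the target
protein, its mRNA, and the used RBP proteins are dropped (complete-case;
logged). The RNA-only model is OLS per outer training fold. The RBP-plus
model penalizes only the RBP block: the intercept and mRNA coefficient are
excluded from the penalty *exactly*, by profiling them out — minimizing
`‖y − Uα − Xβ‖² + λP(β)` over α first shows β solves the same penalized
problem on U-residualized y and X, after which α is the OLS of the
partial residual on U. For ridge, the entire λ path then costs one
eigendecomposition of the (small) residualized Gram matrix per training
split; for lasso the residualized subproblem is delegated to coordinate
descent (`sklearn.linear_model.lasso_path`), with optimality verified in
tests by an independent KKT subgradient check.

The λ grid is shared across genes: 49 log-spaced points on
[1e−4, 1e4] × (mean RBP-column variance) plus an exact infinite-penalty
point at which β_RBP = 0 identically. Including λ = ∞ makes the RBP-plus
family nest the RNA-only model, so the documented convergence behaviour —
uninformative RBPs drive RBP-plus predictions onto RNA-only predictions —
holds exactly at the top of the grid rather than approximately. λ is
chosen per outer fold by 5-fold inner CV *within the training split only*
(no leakage; asserted by instrumentation in the tests), minimizing summed
validation SSE; ties go to the largest λ (parsimony, deterministic).
Outer CV is 5-fold; held-out predictions are pooled across folds and
scored by `R² = 1 − SSE/SST` against the observation mean (this R² can be
negative out of sample). Inner folds match the outer granularity because
the smallest intended panels have ~12 samples. Reported coefficients come
from a final fit on all samples with λ tuned the same way.

Fold assignments are random near-equal partitions, seeded per gene by a
SHA-256 hash of (master seed, gene id), so parallel or re-ordered
execution cannot change results.

## Randomization significance

Each gene's RBP-plus accuracy is referenced to two empirical nulls of
(default) N = 1000 replicates, every replicate refit through the *same*
`fit_rbp_plus` code path with the same fold structure and tuning seeds
(`fit_seed`), so nulls differ from the actual model only in their
predictors:

- **by_rbp** — draw, without replacement, as many proteins as the gene
  has inferred RBPs from the measured-protein pool (excluding the gene's
  own protein — trivial self-prediction — and its actual RBPs; both
  exclusions configurable).
- **by_sample** — permute the sample rows of the RBP block jointly,
  preserving inter-RBP correlation under the null.

The empirical p is `max(#{null R² > actual R²}/N, 1/N)` — strictly
greater, ties do not count, floor exactly 1/N, never 0. A gene is called
**informative** when its RBP-plus R² exceeds its RNA-only R² *and* the
by_rbp raw p < 0.05 (strict). Storey q-values (π0 by the cubic-smoother
λ-grid estimate, λ ∈ {0.05,…,0.95}; with < 10 p-values π0 is fixed at 1)
and BH adjustments are reported alongside; with π0 = 1 the Storey q equals
the BH adjustment exactly. The cohort-level comparison of the two models
is a two-sided Wilcoxon signed-rank test on the per-gene R² differences —
exact sign-assignment enumeration for n ≤ 12, normal approximation with
continuity and tie corrections otherwise.

Calibration, as verified by the acceptance tests: on unregulated synthetic
genes the by_rbp p-values are uniform (KS) with the p < 0.05 fraction near
its nominal level (the max(·, 1/N) floor makes the test very slightly
anti-conservative, ~1/N). Note the two permutation checks test different
nulls: permuting the RBP block leaves the mRNA term intact, so on genes
with a real mRNA effect the by_sample null is centred on the *RNA-only*
accuracy, not on zero; the "null accuracies centred at/below zero" check
is therefore run on genes simulated with no mRNA effect (β_mRNA = 0),
where the two readings coincide.

## Transcript features

Coordinates are 0-based; a uTIS is located by its first base's offset in
the 5'UTR; the annotated TIS (aTIS) sits at transcript offset
len(5'UTR); uTIS distance to the aTIS is the difference of first-base
offsets in nt.

**uORFs** are derived from the uTIS list by two rules: (i) an
out-of-frame uTIS with an in-frame stop codon downstream; (ii) an
in-frame uTIS whose frame terminates before the main start codon, or only
strictly after the main stop codon (the latter describes an
N-terminal-extension-like ORF; the rule is applied as stated rather than
reinterpreted). uORF length runs from the start codon's first base
through the stop codon's last base inclusive, and the ≥ 9 nt minimum is
applied to every uORF (the rules state it for rule (i); applying it
uniformly keeps the length invariant simple, and rule-(ii) ORFs shorter
than 9 nt are degenerate). When uTISs are derived from sequence, the
accepted start set is AUG plus the near-cognates CUG, GUG, UUG, ACG, AUA,
AUU, AUC; a supplied uTIS table is authoritative. The detector is tested
against an independent three-frame enumeration oracle on 1000 random
5'UTRs per run.

**Initiation-context flags** are IUPAC matches centred on the aTIS (+1 =
A of AUG): Kozak `GCCRCCAUGG` (−6…+4), the −3R/+4G minimal context, and
the TIS motif `RYMRMVAUGGC` (−6…+5). Truncated windows yield undefined
flags, logged.

**Associations.** Improvement vs numeric features uses Spearman
correlation (average ranks for ties, two-sided t-approximation, ≥ 10
complete pairs required). The distance profile correlates improvement
with cumulative uTIS counts within (0, d] for a distance grid; windows
with no uTISs anywhere are flagged undefined. Set-valued features use
Fisher's exact test on the (informative × feature) 2×2 table over the
modelled-gene universe; the two-sided p is the sum of hypergeometric
probabilities ≤ the observed table's (the conventional exact definition,
implemented directly so the oracle sweep over all tables with N ≤ 60 is
exact), with the one-sided enrichment tail reported alongside. Generic
category enrichment (GO-slim-style user mappings) uses the hypergeometric
tail in the observed direction with BH adjustment. Informative sets for
enrichment use the nominal p < 0.05 call; q-based variants are emitted
next to them.

## RBP prioritization and transfer

For each informative gene with ≥ 1 retained 5'UTR site and ≥ 1 uTIS, each
uTIS is assigned to the site minimizing the distance between the uTIS
first base and the site's nearest boundary (0 inside the site; the
half-open end coordinate is the downstream boundary; ties broken by
smaller site start, then lexicographic RBP id — fully deterministic).
RBPs are ranked by the number of genes where they own at least one
nearest site; percentages are over eligible genes.

Cross-panel transfer trains RBP-plus models on *all* samples of the
training panel (λ still tuned by inner CV within that panel), restricted
to RBPs measured in both panels, and applies them unchanged to the test
panel. Genes with no shared RBPs fall back to RNA-only and are flagged;
counts reconcile (shared = transferred + skipped). Transferability is the
Spearman correlation between the test-panel accuracies of the transferred
models and of models trained on the test panel itself — chosen because it
reduces to ρ = 1 exactly when the panels coincide and has a clean
permutation null. Both fits share seed derivation so self-transfer is an
identity.

## Synthetic data: what it emulates, what it does not

The generator draws mRNA and RBP protein levels i.i.d. standard normal on
the log scale and builds protein as
`PROT_ij = β0_j + β_mRNA,j·mRNA_ij + Σ_k β_RBP,jk·RBP_ik + ε_ij`,
ε ~ N(0, noise_sd). A configurable fraction of genes is regulated
(nonzero β_RBP); the rest have all β_RBP = 0 exactly. RBP mRNAs are their
protein levels plus noise, so RBPs pass the measured-at-both-levels
restriction. Missingness is completely at random. Defaults (the study
conditions for all tests and the acceptance run): 60 samples, 200 genes,
20 RBPs, 30% regulated, β_mRNA ~ U(0.5, 1.5), β_RBP ~ N(0, 1) with 2–5
RBPs per regulated gene (so RBP terms carry a large share — typically
over half — of protein variance), noise_sd 1, missing rate 2%, uTIS
enrichment odds 3.

UTR backgrounds are i.i.d. uniform over {A,C,G,U} — deliberately the
scanner's exact null, so planted-site recovery and false-positive rates
are analytically checkable. Every nonzero β_RBP,jk is backed by the RBP's
motif consensus planted at a recorded position (one site per interaction
by default, 5' or 3' UTR with equal probability); motifs are sharp
(0.97/0.01) width-8 PWMs, wide enough that a planted consensus survives
BH at FDR 20% across a 200-gene scan. uTISs (AUG with probability 0.6,
else CUG/GUG/ACG) are planted at the configured enrichment odds between
regulated and unregulated genes, at uniform positions subject to an
optional minimum distance from the aTIS; placement uses a non-overlap
allocator that lengthens the UTR and retries (logged) when a plan does
not fit. CDSs are AUG + non-stop codons + UAA. The ledger (truth JSON)
records coefficients, planted sites, planted uTISs, and the uORFs the
planted uTISs induce.

Passing tests on these panels show the pipeline is correct and calibrated
under its own assumptions. They do not show robustness to what real
panels add: measurement physics (iBAQ/spectral-count biases), correlated
expression across genes and samples, informative missingness,
compositional UTR backgrounds, motif redundancy between paralogous RBPs,
or isoform-level ambiguity. Problem sizes in the test suite and the
acceptance script (200 genes, 60 samples, 100–200 randomization
replicates instead of 1000) are desk-scale choices; the statistics do not
depend on them beyond resolution (empirical p floor 1/N).

## Numerical choices and degenerate inputs

- Score grid 1e−3 bits; the DP null's mass is asserted to 1 ± 1e−6.
- Ridge solutions via eigendecomposition of the residualized Gram matrix;
  λ = ∞ handled symbolically (β = 0), never as a large float.
- Inner-CV λ ties → largest λ. Empirical-p ties → not higher.
  Nearest-site ties → smaller start, then RBP id.
- Constant mRNA in a training fold: fold skipped with a warning, gene
  flagged. Constant observations make R² undefined (error, not NaN).
- Genes with < max(k, 6) complete samples are skipped and counted.
- Storey π0 is clipped to [1/m, 1]; fewer than 10 p-values force π0 = 1.
- All file outputs use fixed float formatting and sorted keys; manifests
  hash every artifact (SHA-256), and a rerun with the same master seed
  reproduces the hashes byte for byte.

## Known limitations

- The per-sample noise scale is a single `noise_sd`; per-gene or
  per-sample heteroscedasticity is not simulated (a per-gene option would
  be a natural extension and is noted, not guessed).
- LASSO predictor-selection reporting aggregates nonzero coefficients at
  the chosen λ per outer fold by majority across folds; other
  aggregations are defensible.
- The by_rbp pool excludes the target's own protein and its actual RBPs;
  with very small proteomes this shrinks the pool noticeably.
- Fisher odds ratios are the sample odds ratio ad/bc (inf/undefined
  flagged on degenerate margins), not a conditional MLE.
- `assoc_spearman` requires ≥ 10 complete pairs and uses the
  t-approximation throughout; exact small-n Spearman p-values are not
  implemented since the pair minimum precludes them.
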