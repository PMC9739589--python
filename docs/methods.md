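# Methods

## Scope and data model

`glupart` operates on three objects: a genes × units expression matrix
(units are cells for the single-cell arm, samples for the bulk arm), a
cell annotation mapping each cell to a patient and a population in
{tumor, CD8T, other}, and a clinical table of (time, status, covariates)
per sample. Gene identifiers are matched case-insensitively after
trimming throughout, because public matrices and signature files mix
symbol casings. Survival-time units are declared by the caller, never
inferred.

## Quality control

Cells are retained iff all four hold: detected genes > 50 (strict),
mitochondrial fraction < 4%, ribosomal fraction > 2%, hemoglobin
fraction < 10%. Genes are then retained iff expressed in ≥ 3 of the
surviving cells; the fixed order (cell filter, then gene filter) means
removing cells can never resurrect a gene, and the filter is idempotent.
Two notes:

- Excluding cells with a *low* ribosomal fraction is unusual (most QC
  recipes cap a high one); the rule is implemented exactly as stated in
  the recipe this package reproduces. A threshold of 0 disables it,
  which also matters for data without ribosomal genes (e.g. targeted
  panels and the bundled simulator); the pipeline applies that default
  in simulate mode.
- The mito/ribo/hemoglobin gene sets are identified by configurable
  symbol prefixes (`MT-`, `RPS`/`RPL`, `HB*`), since no explicit lists
  exist for them in the source recipe.

Log-normalization is ln(1 + count / cell_total × 10,000), the standard
CP10K convention; it preserves within-cell expression ranks, which is
all the downstream scoring consumes.

## ssGSEA scoring

For unit *j*, let r_g be the average rank of gene *g*'s expression
within the unit (most-expressed gene has rank N). Walking genes in
descending expression order (ties broken by gene index for determinism),
the raw score is

    S_j = Σ_i [ ECDF_in(i) − ECDF_out(i) ],
    ECDF_in(i) = Σ_{g≤i, g∈sig} r_g^α / Σ_{g∈sig} r_g^α,
    ECDF_out(i) = #{g≤i, g∉sig} / (N − |sig|),

with α = 0.25, the published convention of the single-sample enrichment
algorithm this engine implements (α and the normalization are both
exposed in `SsgseaParams`). When normalization is on, raw scores are
divided by (max − min) over the units scored together.

Two consequences shape the design:

- **Rank invariance.** Any strictly monotone per-unit transform leaves
  scores unchanged, so whether the input layer is counts, CP10K-log, or
  FPKM is immaterial to a single unit's raw score (asserted as a
  property test).
- **The normalization frame matters.** The default scores each
  patient's tumor + CD8T cells jointly, so GStumor and GSimmune share a
  scale within the patient — the minimal assumption under which their
  difference is meaningful. A global frame (all cells together) is
  available (`frame="global"`); which one a published analysis used is
  generally unstated, so the default is a documented choice, not a
  claim.

Signature genes absent from the matrix are dropped with a warning;
scoring refuses to run with fewer than `min_set_genes_present` (default
2) matches, or with a signature covering every gene (empty out-set).

## Dominance score and classification

Per patient: D = median(tumor per-cell scores) − median(CD8T per-cell
scores), computed with the same arithmetic as reported (even-length
medians are the mean of the two central order statistics). A two-sided
Wilcoxon rank-sum test between the two score vectors gates the call:
dominant iff D > 0 and p < 0.05. The boundary p = 0.05 goes to
nondominant (the strict reading of the rule); swapping the population
labels negates D exactly and preserves p.

The Wilcoxon implementation is exact — full enumeration of the rank-sum
null via a subset-sum dynamic program — for tie-free samples with ≤ 10
observations per group, and a tie-corrected normal approximation with
0.5 continuity correction otherwise (`method="approx"` forces the
latter). Degenerate nulls (all pooled values identical) return p = 1.
Whether the original analyses used a continuity correction is not
stated anywhere; the choice is visible only in small or heavily tied
samples.

Group comparisons (CD8T glutamine score, cytotoxicity score, individual
gene expression) pool per-cell values across patients within each group
— matching per-cell box-plot presentations — with a per-patient-median
mode available (`patient_level=True`). No multiple-testing correction is
applied across patients in classification, matching the reproduced
procedure.

## Marker screening and pre-ranked GSEA

Per-gene two-sided Wilcoxon (asymptotic, tie-corrected) between groups;
`avg_logFC = ln((mean(expm1 x_A) + 1) / (mean(expm1 x_B) + 1))` — the
natural-log, +1-pseudocount convention of the common single-cell
toolkits (base-2 by flag). Selection uses the raw gates p < 0.05 and
avg_logFC > 0.25 per direction; BH-FDR is reported alongside but not
used to select, deliberately mirroring the screened procedure.

Pre-ranked GSEA: the classical weighted Kolmogorov–Smirnov running sum
(hit weights ∝ |rank statistic|, exponent 1; signed ES = deviation of
maximal magnitude, |ES| ≤ 1). The nominal p permutes gene labels — the
appropriate null for a pre-ranked list — with add-one smoothing, so
p ≥ 1/(n_permutations + 1); the seed is mandatory.

## Survival arm

Median split: score > median → high, score ≤ median → low; ties at the
median go to low (deterministic and order-independent; with t ties the
high/low imbalance can reach 2t − 1). Kaplan–Meier and the two-group
log-rank test are computed from their closed forms (and cross-checked
against lifelines in tests); with no censoring the KM curve equals the
empirical survival function exactly. Cox models are fit with lifelines
(Breslow ties): each candidate covariate univariately, entrants with
p < 0.2 jointly, with p ≤ 0.05 marking multivariate keepers and a
`force_covariates` option to keep the signature score in the joint model
regardless of its univariate p. Non-convergence (e.g. collinear
covariates) is flagged per covariate, never fatal.

## Synthetic cohorts

`simulate_cohort` draws counts gene-wise from a negative binomial
(gamma–Poisson; variance μ + μ²/size) — the standard overdispersed count
model for scRNA-seq. Defaults, chosen once as a realistic desk-scale
cohort: 10 patients × 100 cells per population, a 500-gene panel
(the 9 glutamine + 6 cytotoxicity genes plus fillers), NB size 2,
mean library size 5,000 (log-normal, CV ≈ 0.25), gene abundances
log-normal. Intended-dominant patients get a log-scale shift δ = 1.5 on
the glutamine genes in tumor cells; intended-nondominant patients get a
log-scale shift of 1.0 on the cytotoxicity genes in CD8T cells (the
dominant group's CD8T cells are the functionally weakened ones). A
two-component cohort (first `n_dominant` patients dominant) emulates a
5/5 split. All randomness flows from one master seed through
per-patient `SeedSequence` substreams, so growing the cohort never
reshuffles earlier patients.

`simulate_survival` draws exponential event times with hazard
baseline × exp(log-HR × standardized score) and independent uniform
censoring U(0, τ), with τ calibrated by bisection so the expected
censored fraction matches the requested rate.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, cell-type compositional variation beyond the 50/50 tumor/CD8T
design, gene–gene correlation, and real signature co-regulation.
Passing tests therefore demonstrate the statistical machinery's
correctness and calibration under the assumed structure, not robustness
to those real-data artefacts.

## Calibration experiments and a rank-leakage caveat

`experiments.dominance_classification_run` measures the classifier's
operating characteristics by simulating patients in memory-bounded
batches and running the full pipeline. One subtlety: because ssGSEA is
purely rank-based, a population shift in *any* genes displaces the
signature genes' ranks and leaks into the signature score. With the
generator's cytotoxicity elevation active in δ = 0 patients, that
leakage alone roughly doubles the null dominant rate. The calibration
and power experiments therefore zero every population shift except the
glutamine effect under study; under that genuinely null configuration
the dominant rate sits near 0.025 — one tail of the two-sided 0.05 gate
intersected with the D > 0 requirement — and power at δ = 1.5 with 100
cells per population exceeds 95%. The same leakage explains why, in the
default mixed cohort, an occasional intended-nondominant patient (whose
CD8T cells carry the cytotoxicity elevation) crosses the dominance
gate: its CD8T glutamine ranks are genuinely depressed. This mirrors the
real-data caveat that rank-based per-cell scores of different
populations are coupled through the whole transcriptome, not just the
signature.

Problem sizes used by the test suite and acceptance script — 2,000
patients for null calibration, 200 for power, 50 Cox replicates at
n = 500, 100 marker-screen permutations over 200 genes — were chosen as
the package's own desk-scale defaults giving stable estimates.

## Numerical choices

- Ties: average ranks everywhere; walk order ties broken by gene index
  (stable sorts), making every score deterministic — no RNG exists
  anywhere in scoring or testing paths, only in simulation and
  permutation p-values, all seeded.
- Score tables round-trip through TSV at `%.17g`, preserving doubles to
  1e-12.
- Matrix Market files are 1-based on disk (the format's convention),
  0-based in memory.
- Exact-vs-approximate Wilcoxon switch at ≤ 10 per group keeps the
  enumeration cheap (≤ C(20,10) configurations via the DP) while
  covering every case where exactness visibly matters.

## Known limitations

- The bulk arm scores samples with the same engine but does not model
  tumor purity or deconvolution; "cancer-cell score" on bulk data is a
  whole-tissue proxy.
- The dominance classification applies no multiple-testing correction
  across patients (by design, matching the reproduced rule).
- Pre-ranked GSEA reports raw ES and nominal permutation p only — no
  NES, FDR across sets, or leading-edge extraction.
- Graph clustering, embedding, batch correction and pseudotime are out
  of scope; population labels are taken as given inputs.
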