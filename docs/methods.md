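# Methods

`dressdx` implements an in-vitro transcriptomic diagnostic for
antibiotic-associated DRESS (drug reaction with eosinophilia and systemic
symptoms). The design rests on a paired challenge: a patient's PBMCs are
cultured for 24 h with the suspected culprit antibiotic or with medium
alone, and drug-induced transcriptional change is measured *within*
subject. Pairing removes the need for population reference ranges — each
subject is their own control — which is what makes the assay plausible as
a routine diagnostic. Two workflows share that backbone:

1. **Discovery** — paired bulk RNA-seq of drug/media PBMC pairs is screened
   for drug-responsive genes, which are distilled into a small biomarker
   panel with expected directions of change.
2. **Validation / diagnosis** — the panel is measured on an RT-qPCR array
   card; each subject's per-gene log2 relative quantities are scored for
   directional concordance with the signature, and the integer score is
   thresholded into a positive (drug-hypersensitive) or negative call.

## Normalization

Counts are filtered with the rule *keep a gene iff it has ≥ 2 counts in at
least half (ceiling) of the samples*. The phrase "filtering out genes less
than 2 gene counts in at least half of the samples" admits a second reading
(remove a gene when it is low in at least half the samples, i.e. keep when
it is high in more than half); the two differ only for even sample counts
with an exact tie. We use the keep-reading above, stated here rather than
assumed silently.

Between-sample scaling uses the trimmed mean of M-values (TMM). For sample
*k* against reference *r* (the sample whose 75th-percentile count fraction
is closest to the across-sample mean), gene-wise log-ratios
M = log2((y_k/N_k)/(y_r/N_r)) and abundances A = ½·log2((y_k/N_k)(y_r/N_r))
are formed over genes counted in both samples; the central 40% of M (30%
trim each side) intersected with the central 90% of A (5% each side) is
averaged with inverse delta-method variance weights
(N−y)/(Ny) + (N_r−y_r)/(N_r y_r), and the factor is 2 to that mean.
Factors are renormalized to geometric mean 1. These details (reference
choice, 30%/5% trims, precision weights, zero exclusion) follow the
canonical published TMM procedure; during development the factors were
checked to agree with the reference implementation to 6 decimal places,
and the test suite holds them to an independent step-by-step
reimplementation at 1e-6. Expression is reported as cpm over
TMM-effective library sizes: cpm[g,s] = counts[g,s]/(N_s·f_s)·1e6.

## Paired differential expression

Each gene is summarized per subject by d_i = log2((cpm_drug+c)/(cpm_media+c))
with pseudo-count c = 0.5, and tested with a sign-flip permutation of the
paired t statistic t = mean(d)/SE(d) (SE with n−1). Under the null of no
drug effect, the d_i are sign-symmetric, so all 2^n sign assignments are
equally likely; p is the fraction of assignments with |t*| ≥ |t|, identity
included (hence p > 0). All 2^n flips are enumerated for n ≤ 12 pairs;
larger designs use Monte-Carlo flips with the identity forced in.
Multiplicity is controlled with Benjamini-Hochberg step-up q-values.

This permutation test replaces a negative-binomial GLM: it is
self-contained, exactly testable, and assumption-light for a paired
design. Its price is **granularity**: the smallest attainable exact p is
2^(1−n) (both t and −t always tie |t|). Two consequences are worth
stating plainly:

* With 5 pairs (the study's discovery size) the minimum p is 2/32 =
  0.0625, so *no* gene can reach q ≤ 0.05; the pipeline run at that size
  demonstrates effect-size recovery (planted |log2 FC| = 2 estimated
  within ±0.3) but can honestly select nothing. Parametric count models
  exist precisely to buy power at such sizes.
* Calibration and recovery analyses therefore use sizes where the null
  distribution has mass below the cut: type-I calibration at 8 pairs
  (attainable p ≤ 0.05 mass = 6/128 ≈ 0.047, so the expected fraction of
  null genes at p ≤ 0.05 sits inside [0.03, 0.07]), and signature
  recovery at 16 pairs with 20 000 Monte-Carlo flips, where the p floor
  clears BH across 2000 genes with margin. These sizes are fixed by the
  arithmetic above, not by experiment.

## Panel selection

Candidates must pass q ≤ 0.05, |logFC| ≥ 1.5, per-gene minimum cpm ≥ 4 and
maximum cpm ≥ 100 across all samples (an unexpressed biomarker is useless
on a card regardless of its fold-change). Candidates are ranked by
impurity (gini) importance from a 500-tree random forest classifying drug
vs media samples on log2 cpm, seeded for determinism; up to ten genes with
|logFC| ≥ 2 and normalized importance ≥ 0.05 are selected (ties at the cap
broken by |logFC|, then gene id) and combined with an optional curated
immune-gene list. Directions come from the sign of the discovery logFC.
Because importances are normalized to sum 1 over candidates, the 0.05 cut
acts as a top-k concentrator, not a recovery device: with many
equally-informative markers it deliberately keeps only the sharpest few.
Recovery of a planted signature is therefore assessed at the candidate
stage, with panel membership assessed for precision (selected ⇒ planted).

Marker combinations are evaluated by a combinatorial ROC: each marker is
direction-adjusted, dichotomized at its Youden-optimal cutoff (ties toward
the more sensitive cutoff), a subject's combination score is its count of
positive markers, and that count is swept as the ROC threshold. All
2^k − 1 subsets of up to 10 markers are enumerated; a subset is flagged
useful when sensitivity > 85%, specificity > 85% and AUC ≥ 0.8. With 13
subjects and per-marker cutoffs fitted on the same data these in-sample
metrics are optimistic; the label-permutation control in the tests shows
the pass flag is still not reachable by chance at that size.

## qPCR quantification and scoring

Array-card technical duplicates are collapsed by arithmetic mean.
Undetermined wells are dropped rather than imputed at Ct 40 (imputation
fabricates fold-changes); a well pair that loses a replicate, spreads more
than 1 cycle, or disappears entirely is flagged for QC. Relative
expression uses the double-delta-Ct rule against the single housekeeping
gene YWHAZ: ΔCt = Ct_target − Ct_YWHAZ per condition, ΔΔCt = ΔCt_drug −
ΔCt_media, log2 RQ = −ΔΔCt. A missing housekeeping well is fatal for that
subject (it anchors every gene); a missing target is a flagged gap.

Scoring: each panel gene with |log2 RQ| > 0.25 contributes +1 if its sign
matches the signature direction and −1 otherwise; values in the dead zone
[−0.25, 0.25] (boundary inclusive — "between −0.25 and 0.25" is read as
the closed interval) contribute nothing, as do missing genes. The summed
integer score is thresholded: the 22-gene workflow calls positive at
score ≥ 6; the reduced 6-gene panel (STAC+, GPR183−, CD40, CISH+, CD4−,
CCL8+; CD40's direction is not stated in the source text and is shipped
marked "unspecified" with an up default) uses threshold 0 with the strict
convention (> 0). The strict choice at zero is forced by coherence: a
subject with no net signal scores exactly 0, and a diagnostic that calls
"no signal" positive would have zero specificity on quiet controls. The
boundary convention is exposed as a flag (`inclusive`) because the
per-subject scores that would pin it are not public.

Cohort evaluation reports the 2×2 confusion table (exact rational
sensitivity/specificity), a two-sided Fisher exact p on the calls, and an
exact Mann-Whitney p on the raw scores.

## Exact tests

Fisher's two-sided p uses the point-probability convention: the sum over
all tables with the observed margins whose hypergeometric probability does
not exceed the observed table's. Probabilities are compared as exact
integer numerators over a common binomial denominator, so no tolerance
enters. Mann-Whitney uses U = #{x>y} + ½#{x=y} and doubles the smaller
exact tail over all C(n₁+n₂, n₁) assignments, capped at 1; pooled sizes
above 25 fall back to a tie-corrected, continuity-corrected normal
approximation and are flagged. Negative ("Neg") ELISpot entries enter rank
tests as rank-minimal zeros. These two conventions jointly reproduce all
six assay/confusion p-values printed in the source tables at two
significant figures, which is what fixes them among the several defensible
two-sided definitions. Pearson correlation excludes incomplete pairs and
refuses zero-variance input rather than returning 0.

## Synthetic cohorts

The generator emulates the study's two data modalities, with defaults set
to the study conditions: discovery 5 allergic subjects (drug/media pairs),
validation 6 allergic + 7 tolerant; ~12k expressed genes; planted effect
|log2 FC| = 2, half down-regulated; qPCR duplicate wells with 0.1-cycle
log2-RQ noise.

* **Counts**: gene means are log-normal on the count scale (meanlog 3,
  sdlog 1.5 — a conventional bulk abundance spread; the source reports no
  dispersion or library statistics to fit), scaled by a per-subject
  log-normal library size clipped to [0.5M, 2M], with negative-binomial
  noise at common dispersion 0.1. Allergic drug-condition signature genes
  are multiplied by 2^(±effect). Signatures are planted on well-expressed
  genes (expected cpm ≥ 150): the selection cascade's abundance floors
  make a signature on unexpressed genes undetectable by construction, and
  the real panel was itself abundance-filtered.
* **Cards**: per-gene base Cts are uniform in [22, 30] (housekeeping at
  20), a per-subject loading offset cancels in ΔCt, allergic drug-side
  target Cts shift by −(planted log2 FC), and every well receives Gaussian
  noise of sd qpcr_noise_sd/√2, which propagates through duplicate
  collapse and ΔΔCt to a log2-RQ sd of exactly qpcr_noise_sd.

What the generator does **not** model: batch or lane effects, gene-gene
correlation, subject-specific effect heterogeneity, amplification
efficiency differences, undetermined-well censoring at high Ct, or any
relation between the card genes and real immune biology. Passing recovery
tests therefore show the pipeline's statistics are correct and calibrated
on data matching its own assumptions — not that the six real genes
diagnose real patients.

## Problem sizes and numerical choices

Tests and the acceptance script run the discovery screen at 2000 genes
(16 or 8 pairs as above), classification at 20 seeded validation cohorts
(260 subject calls), and the exact-test oracles over every 2×2 table with
n ≤ 40 and pooled Mann-Whitney sizes ≤ 12 — sizes chosen so the whole
suite completes in well under a minute on one core while keeping every
combinatorial check exhaustive. Determinism: every stochastic step takes
a seed (NumPy `default_rng`); identical config+seed gives byte-identical
outputs. Degenerate inputs are decided, not accidental: all-zero DE genes
get p = 1, constant non-zero genes get the 2^(1−n) floor, degenerate
Fisher margins give p = 1, zero-variance correlation raises, an all-flat
random forest warns and returns uniform importances, and file writes are
atomic (temp + rename).

## Known limitations

* The permutation DE test cannot reach FDR significance at 5 pairs (see
  above); it is a deliberate trade of power for exactness.
* Combinatorial ROC metrics are in-sample; no cross-validation is done at
  these cohort sizes.
* The printed DEG counts (267; 149 up/118 down), the 48-candidate count,
  the exact 22-gene list, the cross-platform r = 0.954 and cross-disease
  correlations, and the full-data combinatorial AUC = 1 depend on the
  deposited cohort data and supplementary material and are not reproduced
  here; the planted-signature recovery, precision, concordance, and
  permutation-control suites stand in for them at synthetic scale.
* Thresholds 6 and 0 are taken as given for their panels; no threshold
  re-optimization is attempted.
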