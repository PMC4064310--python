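# Methods

`respanel` re-creates, as tested code, a two-cohort blood-transcriptomics
workflow for predicting response to anti-TNFα (infliximab) therapy in
Crohn's disease (CD) and rheumatoid arthritis (RA): univariate screening
of a microarray *test* cohort, qPCR measurement of the screened genes in
an independent *validation* cohort, and discovery of multi-gene panels
that separate responders from non-responders with a linear discriminant
classifier wrapped in a backward-elimination search.

## The classifier

For two classes, canonical variates analysis (CVA) coincides with
Fisher's linear discriminant (LDA). Given a gene panel with per-class
mean vectors μ_R, μ_N and pooled within-class covariance S_W, the single
canonical axis is

    w = S_W⁻¹ (μ_R − μ_N),

the direction maximizing the between-group to within-group scatter
ratio. A sample x gets the canonical score w·(x − x̄) (centered at the
training grand centroid) and is called a responder when its projection
exceeds the midpoint of the projected class means shifted by the log
prior ratio ln(π_R/π_N); priors are the empirical class proportions,
because the cohorts are imbalanced (e.g. 13 vs 7). A score exactly on
the cut goes to the larger-prior class.

Panels routinely hold more genes than there are patients (up to 91 genes
on ≤ 20 samples), making S_W singular. We add a ridge of
`1e-6 × mean(diag(S_W))` to the diagonal before solving — deterministic,
close to pseudo-inverse behaviour, and negligible on well-conditioned
fits (the Fisher-direction oracle tests pass with ridge 0 on
non-singular toys). The ridge is exposed everywhere as a parameter.

Equal class covariances are assumed throughout (LDA, not QDA), and only
the binary responder/non-responder case is supported.

## The panel search

Backward elimination around the classifier, with per-gene F-values
(one-way ANOVA between/within variability ratio) computed **once** on
the full starting matrix:

1. `genes_in_model` ← all genes; `already_tested` ← ∅;
   `best_accuracy` ← accuracy(`genes_in_model`).
2. While `genes_in_model − already_tested` is non-empty:
   pick a gene from that set by the selection model
   (**uniform**: equiprobable; **f_prop**: probability ∝ 1/F;
   **min_f**: deterministic argmin of F, lexicographic tie-break),
   remove it temporarily, and recompute accuracy.
   - If accuracy dropped: reinsert the gene and mark it tested.
   - Otherwise: remove it permanently, empty `already_tested`, and raise
     `best_accuracy` to the new value.
3. Return the surviving genes, `best_accuracy`, and the full removal log.

Each iteration either shrinks the gene set or grows the tested set, so
the number of classifier fits is bounded by O(n_genes²); the tests
assert the bound and replay every removal log. The acceptance rule is
"at least as good", so the returned panel's accuracy never falls below
the full starting set's — also asserted on every run.

`f_prop` edge cases are not defined by the procedure itself, so we fix
them: F = +∞ (perfectly separating gene) gets weight 0 unless all genes
are infinite (then uniform); F = 0 gets ten times the largest finite
1/F among the candidates — strongly but not exclusively preferred.

The in-loop accuracy metric defaults to resubstitution (the search first
hunts for panels that segregate the training cohort perfectly; LOOCV is
then computed per returned panel), with `metric="loocv"` available to
drive the search by cross-validation instead. `search_panels` runs the
stochastic models `n_restarts` times (default 100) from substreams keyed
by (seed, model code, restart index) — results are independent of the
order models are listed — runs min-F once, deduplicates identical gene
sets keeping the earliest, and annotates every panel with LOOCV accuracy,
per-sample held-out canonical scores, and ROC-AUC.

## Evaluation

LOOCV refits the model n times on n−1 samples; the held-out sample's
canonical score (centered at that fold's training centroid, axis
oriented responder-high) feeds the ROC curve. The trapezoid AUC equals
the tie-corrected pair-counting statistic
P(score_R > score_N) + ½P(equal); ties get half credit because scores
from 20-patient cohorts can tie.

Gene ranking follows the published procedure: restrict to panels with
LOOCV accuracy **strictly above** the threshold (default 80%), count
each gene's appearances, sort by count descending then gene id; genes
present in the pool but in no qualifying panel are listed with count 0.

### Optimism, and what LOOCV does and does not control

Two systematic effects matter at this cohort size and are deliberately
left visible rather than corrected:

- **Selection optimism.** Panels are selected using *all* samples, so
  the LOOCV accuracy of a selected panel is biased upward on null data
  (the classic wrapper-selection bias). Measured on 100 effect-free
  13v7 cohorts with 20 genes, searched-panel LOOCV averages ≈ 6 points
  above the 65% majority rate. Honest out-of-sample assessment of a
  *discovered* panel requires an external cohort.
- **Leave-one-out class depletion.** For a *fixed* panel on null data,
  removing the held-out sample depletes its own class in training, which
  biases null LOOCV accuracy slightly *below* the majority rate; the
  held-out AUC stays unbiased at 0.5.

The null-calibration tests bracket both effects: searched-panel LOOCV
mean within 10 points of the majority rate, fixed-panel AUC 0.5 ± 0.06
over 100 simulated cohorts.

## Univariate screening

- **Low-intensity filter**: genes ranked by mean linear intensity across
  samples; exactly ⌊fraction × n_genes⌋ lowest removed (default 0.2).
  Ties at the cutoff break by (mean, gene id). The summary statistic
  (mean) is a package choice.
- **Mann-Whitney U**: U = min(U_x, U_y) with half credit for ties.
  The two-sided p is exact — enumeration of all C(n, n₁) group
  assignments, valid under ties — for combined n ≤ 12, matching the
  cohort scale; larger samples use the normal approximation with tie and
  continuity corrections (the two routes agree within 0.02 at 6v6).
- **Fold change**: ratio of linear-scale group means, direction-agnostic
  (≥ 1) plus a sign for up/down in responders; a zero denominator group
  mean reports +∞ with a valid direction. Cutoff default 1.5.
- A gene passes when p < α (default 0.05) **and** FC ≥ cutoff. No
  multiple-testing correction by default (matching the original
  unadjusted screen); Benjamini–Hochberg is available behind a flag.
- The baseline vs week-2 contrast reuses the same unpaired test;
  pairing is not assumed.

## Comparative-Ct normalization

Relative expression of target gene g in sample s is
2^−(Ct[g,s] − Ct[ref,s]) with PPIA as the default reference.
Housekeeping assays are excluded from the output; `Undetermined`/`NA`/
empty Ct tokens become missing values, a missing reference Ct makes the
whole sample's values missing, and any gene missing in any sample is
excluded from multivariate stages (listwise by gene — LDA needs complete
vectors).

## The cohort simulator

The generator exists so every downstream stage is testable without any
data download. Per gene g and sample s,

    log2 x[g,s] = m[g] + δ[g]·1{s responder} + σ·z[g,s],

- m[g] ~ N(base_log2_mean = 8, gene_level_sd = 2): per-gene baseline
  abundance shared by both groups — this spread is what the
  low-intensity filter acts on;
- δ[g] = ±effect_size·σ for the first `n_informative` genes, sign
  alternating (real panels mix up- and down-regulated genes), 0
  otherwise; `effect_size` is therefore a standardized (Cohen's d) shift;
- z standard normal with exchangeable correlation `block_correlation`
  inside consecutive blocks of `block_size` informative genes (one-factor
  construction), independent elsewhere. The correlation structure among
  the real card genes is unknown; blocks are a modeling choice.

Linear-scale expression is 2^log2x, so values are strictly positive.
Default cohort sizes mirror the validation cohorts (CD 13/7; RA 4/11
available via config); default card size 91 genes with 10 informative at
effect 2.0 — strong enough that perfectly segregating panels exist, as
in the original cohorts.

The qPCR readout is Ct = 30 − log2(x) + N(0, ct_noise_sd²) (default
noise 0.25 cycles), clipped to the instrument range (0, 45]; the five
housekeeping assays (ACTB, GAPDH, HPRT1, PPIA, RPLP0) are appended with
unit expected expression, i.e. group-independent constant expected Ct.
With zero noise, comparative-Ct normalization inverts the readout
exactly (round-trip test).

Clinical covariates are truncated-normal draws per (disease, covariate,
responder group) with the means/SDs transcribed from the published
cohort summaries (packaged fixtures `cd_clinical.yaml`,
`ra_clinical.yaml`: CD CDAI 319.6±41.3 responders vs 351.5±33.1
non-responders, RA DAS28 5.6±0.3 vs 5.2±0.7, etc.) and physiological
truncation bounds (CDAI ≥ 0, DAS28 ∈ [0, 9.4], HAQ ∈ [0, 3],
neutrophils ∈ [0, 100] %…). Truncation is far from the means, so sample
means recover the configured values within 2 SE at n = 10,000.

One global integer seed drives purpose-named substreams (expression /
Ct noise / covariates / search restarts), so adding or rerunning one
stage never perturbs another's draws; every generator is a pure function
of (config, seed), and repeated runs are byte-identical.

**What the simulator does not emulate:** probe-level array artifacts,
batch effects, qPCR dropout beyond missing-value handling, week-2
pharmacodynamic trajectories, and realistic gene–gene correlation
outside the informative blocks. Passing tests therefore demonstrate the
*procedures* behave as specified under a known generative model, not
that any particular gene list generalizes to patients.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
oracle checks use ≤ 6-gene toys with exhaustive subset enumeration;
calibration suites use 100 simulated 13v7 cohorts of 8–20 genes; the
end-to-end check uses the full card scale (91 genes × 20 samples, 50
restarts × 3 selection models with LOOCV annotation), which completes in
a few seconds. The strong-signal acceptance condition is 40 genes × 20
samples with 10 informative genes at effect 2.5.
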