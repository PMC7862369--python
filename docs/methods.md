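# Methods

## The model

`imsig` operationalizes a two-axis view of the tumor microenvironment: an
inflammation axis, read out by a 10-gene IFN-γ signature (cytotoxic cells,
antigen presentation, IFN-γ activity), and a suppression axis, read out by
an immunosuppression signature (IMS) of genes marking cancer-associated
fibroblasts, tumor-associated macrophages and their cytokines. The working
hypothesis is that ICI benefit requires inflammation *in excess of*
suppression, so the biomarker is the log-domain ratio

    r_s = mean_{g in IFN-γ} x_gs − mean_{g in IMS} x_gs

computed on log2, housekeeping-normalized expression `x_gs`. Because both
terms are means over the same sample, any additive per-sample offset
(sequencing depth, global normalization error) cancels exactly; the test
suite asserts this shift invariance to 1e−9.

### Discovery

IMS genes are learned from cohorts with RECIST response labels:

1. log2(FPKM + 1); per-sample subtraction of the mean log2 expression of 20
   housekeeping genes.
2. Per-sample IFN-γ score; the score is subtracted from every gene of that
   sample (log-domain division), removing the inflammation axis so the
   *t*-test isolates suppression-specific elevation. Subtraction (rather
   than linear-domain division) is the only reading consistent with
   log-scale scores.
3. Per cohort, a one-sided two-sample Student's *t*-test (pooled variance,
   upper tail) of PD versus CR/PR per gene; SD samples are excluded.
   Zero-variance genes receive p = 0.5 / 0 / 1 by the sign of the mean
   difference.
4. Pearson's combination across cohorts: X = −2 Σ ln(1 − pᵢ), combined
   p = P(χ²₂ₖ ≤ X). This left-tail form uniquely satisfies two properties
   the pipeline relies on: it reduces to the identity at k = 1, and it is
   driven by the *largest* pᵢ, so one cohort's null result vetoes a gene no
   matter how significant the others are. Fisher's method (right tail on
   −2 Σ ln pᵢ, driven by the smallest pᵢ) is available for comparison only.
5. Rank by combined p, ties broken lexicographically by gene symbol
   (platform-independent determinism); select the top K = 18.

Cohorts are never pooled: testing each dataset separately and combining
p-values is the batch-effect defense; the synthetic generator plants
per-cohort per-gene batch offsets precisely to keep this property exercised.

### Evaluation conventions

- AUC is Mann–Whitney concordance (ties 1/2), computed on CR/PR versus PD
  with SD excluded. CI: DeLong by default (deterministic), stratified
  bootstrap (2000 resamples, seeded) optionally.
- The Youden cutoff maximizes J = sensitivity + specificity − 1 over the
  finite thresholds of the ROC; the reported cutoff is the midpoint between
  the two bracketing distinct scores, and J-ties resolve toward the lower
  cutoff (the larger predicted-responder group). "Predicted responder"
  means score strictly greater than the cutoff; with midpoint cutoffs
  strictness is immaterial.
- Two responder dichotomies are explicit flags, never inferred: `crpr`
  (CR/PR vs PD, SD dropped — the AUC convention) and `disease_control`
  (CR/PR/SD vs PD — the convention under which the published
  confusion-table narrative counts SD among patients who benefited).
- Fisher's exact test is two-sided by hypergeometric enumeration of all
  tables with the observed margins (probability-at-most-observed rule, with
  a 1e−7 relative slack against float round-off).
- Mann–Whitney is exact by enumeration of group assignments for combined
  n ≤ 12 (handles ties), otherwise normal approximation with tie
  correction. Wilcoxon signed rank drops zero differences, uses average
  ranks, and is exact via a subset-sum recursion over sign assignments for
  n ≤ 20 (doubled ranks keep the support integral), otherwise normal with
  continuity correction. Both report 2·min(lower, upper) tails, capped at 1.
- Survival: Kaplan–Meier curves, the standard hypergeometric-variance
  log-rank test, and a single-covariate Cox model (Efron ties, Wald CI) via
  lifelines. Complete separation is flagged (`unbounded=True`) after a
  small-ridge refit rather than reported as a spuriously precise CI.

### Leave-datasets-out robustness

All C(n, 3) discovery/validation splits are enumerated deterministically in
lexicographic order — for seven cohorts, exactly 35. ("Randomized test"
terminology notwithstanding, 35 equals the complete enumeration, so nothing
is left to chance; a seeded subsample is available for larger collections.)
Per split, the IMS is rediscovered on the three discovery cohorts and the
IFN-γ/IMS ratio plus fixed comparator signatures are scored on each held-out
cohort. Per-cohort normalization does not depend on the split, so prepared
matrices are computed once and reused across all 35 runs. AUCs are recorded
per (split × validation cohort); the cross-method Wilcoxon comparison uses
per-split medians over validation cohorts by default (the aggregation is
configurable because pooling per split, per cohort, or per pair are all
defensible). Splits whose discovery arm fails the ≥2-per-arm *t*-test
precondition are skipped and recorded, never silently dropped; gene-
frequency totals therefore equal completed-splits × 18 exactly.

## The synthetic generator

`generate_cohorts` emulates the statistical structure the analysis assumes,
not RNA-seq counts: the pipeline consumes log2 FPKM and is mean-shift based,
so a Gaussian log2-scale model is the right level of realism and a
negative-binomial count layer would add nothing testable.

Per sample, latent inflammation a and suppression b are standard bivariate
normal with correlation ρ = 0.5. Gene values are
`x_gs = μ_g + λA_g·a_s + λB_g·b_s + batch_cg + ε_gs` with μ_g ~ N(5, 2²)
shared across cohorts, batch offsets N(0, 0.5²) redrawn per cohort and gene,
and noise sd σ = 1. The 10 IFN-γ genes carry λA = 1; the 18 planted
suppression genes carry λB = 1 plus λA·0.3 (inducing the positive
correlation observed between the two scores, r ≈ 0.6 pooled); the 20
housekeeping genes carry no loadings and σ/5 noise; background genes carry
no loadings. The candidate universe holds 770 genes (IFN-γ + planted +
background), echoing a curated cancer-immune panel; the housekeeping genes
sit in the expression matrix but *outside* the universe — normalization
reference genes are a separate panel class and are never signature
candidates.

Clinical benefit is `u = β0 + βa·a − βb·b + ε` with β0 = 0, βa = βb = 1 and
ε sd 0.5 — chosen once as a symmetric, substantially-but-not-fully
deterministic outcome model. RECIST labels come from thresholding the
z-score of u at 0.36 (PD below) and 0.75 (CR/PR above; CR above 1.95),
giving ≈ 64% PD / 13% SD / 23% CR+PR, the outcome mix of a real anti-PD-1
melanoma cohort. Thresholds are defined on the z-scale (u standardized by
its analytic sd) so the marginal mix survives any coefficient setting,
including fully null configurations. Survival is exponential with log-hazard
γ0 − γ1·u (γ0 = −3 per month, γ1 = 0.5) under administrative censoring at 36
months. Cohort sizes default to 3 × 40 (7 × 40 for the robustness demo).
All draws come from one `numpy` Generator seeded by the mandatory config
seed; identical configs are bit-identical.

What the generator does **not** emulate: count-level noise, per-sample
library-size artifacts (the ratio's shift invariance makes them moot),
gene–gene correlation beyond the two factors, cell-type mixtures, or
tumor-type heterogeneity. Passing tests on this generator therefore
demonstrate the *statistical machinery* — not that the signature
generalizes to real patients, which requires the external cohorts.

### Controls and what they show

- **Positive control**: discover on two cohorts, score the third held out;
  the ratio's median held-out AUC over 10 seeds is ≈ 0.91 at default effect
  sizes.
- **Negative control**: with all expression–response couplings removed
  (λB = βa = βb = 0), the same pipeline yields median held-out AUC ≈ 0.55,
  inside [0.35, 0.65] — rediscovery does not manufacture signal, and
  planted-gene recovery collapses to the hypergeometric chance rate
  (≈ 18²/770 ≈ 0.4 genes). Note the inflammation coupling must be nulled
  too: with βa > 0 the IFN-γ half of the ratio predicts response by design,
  and a "null" in the suppression axis alone still shows AUC ≈ 0.95.
- **Recovery**: at default conditions discovery recovers a median ≈ 12 of
  18 planted genes over seeds. The known limitation behind the imperfect
  recovery: subtracting the IFN-γ score imprints −a on every gene without
  an inflammation loading, and since a predicts response, all ~740
  background genes share a systematic uplift-in-PD artifact at roughly 0.6×
  the planted genes' standardized effect; the upper order statistics of
  that many correlated artifact carriers displace mid-tier planted genes.
  This is a property of covariate-adjustment-by-subtraction itself, worth
  remembering when interpreting real discovery runs: genes anti-correlated
  with inflammation are systematically favored.

## Numerical choices

- Pseudocount 1.0 in log2(FPKM + 1): maps 0 to 0, the standard choice.
- p-values are clipped to [1e−15, 1 − 1e−15] before ln(1 − p), so a cohort
  p of exactly 1 cannot overflow the combination.
- PC1 scores (comparator archetype) come from an SVD of the gene-centered
  submatrix and are sign-oriented to correlate positively with the
  signature-gene mean, fixing the inherent sign ambiguity across linear-
  algebra backends. Pair-sum scores count strict inequalities only; ties
  score 0.
- Missing expression cells are rejected, never imputed: score definitions
  assume complete per-gene vectors, and gene-level (not cell-level)
  exclusion is already defined for absent genes. Duplicate gene rows are
  mean-collapsed with a warning; gene symbols are uppercased and matched
  exactly (no alias resolution).
- The reader imposes no abundance filter on genes; the candidate universe
  is a required, user-supplied input for discovery on real data (the
  commercial 770-gene panel membership is not redistributable).

## Problem sizes

Defaults throughout are desk-scale: 770 + 20 genes, 40 samples per cohort,
3 cohorts for discovery runs and 7 for the robustness demo (35 splits,
≈ 8 s end to end); stochastic controls use 10 fixed seeds. These sizes make
every documented number reproducible in seconds while keeping the test
statistics in their asymptotically meaningful regimes.
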