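# imsig

Discovery and evaluation of an **immunosuppression signature (IMS)** for
predicting response to immune checkpoint inhibitors (ICIs) from bulk RNA-seq.

An inflamed, IFN-γ-high tumor microenvironment is necessary but not
sufficient for benefit from anti-PD-1 therapy: suppressive elements —
cancer-associated fibroblasts, tumor-associated macrophages and their
cytokines — can block an otherwise primed immune response. `imsig`
implements a pipeline that quantifies this balance:

1. **Normalization** — expression is log2-transformed (`log2(FPKM + 1)`) and
   each sample is self-normalized by subtracting its mean log2 expression of
   20 stable housekeeping genes.
2. **Signature discovery** — within each cohort independently (avoiding
   cross-dataset batch effects), every candidate gene is adjusted by the
   sample's 10-gene IFN-γ score and tested with a one-sided pooled-variance
   Student's *t*-test for elevation in nonresponders (PD) versus responders
   (CR/PR), SD excluded. Per-cohort p-values are combined with **Pearson's
   method**, the left tail of χ²₂ₖ on X = −2·Σ ln(1 − pᵢ), which is dominated
   by the *largest* pᵢ — a gene must be consistent in every cohort. The top
   K = 18 genes by combined p form the IMS.
3. **Scoring** — the biomarker is the log-domain ratio
   `IFN-γ/IMS = mean(IFN-γ genes) − mean(IMS genes)`; any per-sample
   additive offset cancels, making the score self-normalizing.
4. **Evaluation** — SD-excluded ROC/AUC (Mann–Whitney concordance, DeLong or
   bootstrap CI), Youden-index cutoff selection, Fisher-exact confusion
   analysis, Mann–Whitney group comparison, Kaplan–Meier/log-rank survival
   stratification and a two-group Cox hazard ratio.
5. **Robustness** — the leave-datasets-out test: for each of the
   C(7,3) = 35 discovery/validation splits of a 7-cohort collection, the IMS
   is rediscovered and evaluated on the held-out cohorts; gene occurrence
   frequencies measure selection stability and a Wilcoxon matched-pairs
   signed rank test compares methods.

A seeded synthetic-cohort generator (`imsig.simulate`) provides multi-cohort
data with planted ground truth — latent inflammation and suppression factors,
per-cohort batch offsets, RECIST labels and censored survival — so the whole
pipeline is exercisable and testable without access to patient data.

## Worked example

One command simulates seven cohorts (40 patients each, default effect
sizes) and runs the full leave-datasets-out robustness test:

```bash
imsig demo --seed 0 --out-dir scratch/demo
```

Output (abridged):

```json
{
 "splits": 35,
 "gene_occurrences_total": 630,
 "planted_in_top23": 17,
 "method_summary": {
  "IFNG/IMS": {"median": 0.903, "mean": 0.896, "min": 0.826, "max": 0.941},
  "IFNG_10":  {"median": 0.728, "mean": 0.728, "min": 0.711, "max": 0.749}
 },
 "wilcoxon_p": 2.59e-07
}
```

Reading this: all 35 discovery/validation splits completed, tallying
35 × 18 = 630 gene occurrences; 17 of the 23 most frequently selected genes
are truly planted suppression genes; the rediscovered IFN-γ/IMS ratio
reaches a median held-out AUC of 0.90 versus 0.73 for the IFN-γ score
alone, a difference the paired Wilcoxon test calls highly significant.

The same stages are available as subcommands (`simulate`, `score`,
`discover`, `evaluate`, `robustness`) and as library functions. The
discovery/scoring core is also packaged as a scikit-learn-style estimator:

```python
import pandas as pd, numpy as np
from imsig import IMSRatioClassifier, SyntheticConfig, generate_cohorts

cohorts, truth = generate_cohorts(SyntheticConfig(seed=11))
X = pd.concat([c.expression.values.T for c in cohorts])   # samples x genes
y = pd.concat([c.clinical.response for c in cohorts])     # CR/PR/SD/PD
groups = np.concatenate([[c.name] * c.n_samples for c in cohorts])

clf = IMSRatioClassifier(k_top=18).fit(X, y, groups=groups)
clf.ims_genes_        # the 18 learned suppression genes
clf.decision_function(X)   # IFN-γ/IMS ratio scores
clf.predict(X)             # 1 = predicted responder (Youden cutoff)
```

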