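"""scikit-learn-style estimator wrapping discovery, scoring and classification.

`IMSRatioClassifier.fit` learns the immunosuppression gene set from labeled
training cohorts (per-cohort one-sided t-tests combined with Pearson's
method) and a Youden-optimal decision cutoff on the training ratio scores;
`decision_function` returns IFN-g/IMS ratio scores for new samples and
`predict` thresholds them. The estimator composes with sklearn model
selection: ``groups`` plays the cohort role, so LeaveOneGroupOut reproduces
a leave-dataset-out evaluation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .containers import ClinicalTable, Cohort, ExpressionMatrix
from .discovery import discover_ims, score_ratio_on_cohort
from .evaluation import roc_auc, youden_cutoff
from .genesets import GeneSignature, HK_20, IFNG_10


def _as_expression(X, scale: str) -> ExpressionMatrix:
    """Accept samples x genes DataFrame (sklearn orientation) or ExpressionMatrix."""
    if isinstance(X, ExpressionMatrix):
        return X
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a pandas DataFrame (samples x genes) with "
                        "gene-symbol columns, or an ExpressionMatrix")
    return ExpressionMatrix(X.T, scale_tag=scale)


class IMSRatioClassifier(ClassifierMixin, BaseEstimator):
    """Learn an immunosuppression signature and classify by IFN-g/IMS ratio.

    Parameters
    ----------
    k_top : int, default 18
        Number of suppression genes to select.
    universe : sequence of str or None
        Candidate genes for discovery. None means every gene shared by all
        training cohorts except the IFN-g and housekeeping fixtures.
    combine : {"pearson", "fisher"}
        p-value combination across cohorts.
    pseudocount : float
        Pseudocount for log2 transform of linear-FPKM input.
    input_scale : {"log2", "linear_fpkm"}
        Scale of DataFrame inputs (ExpressionMatrix inputs carry their own tag).
    ifng_genes, hk_genes : sequences of str
        Inflammation-signature and housekeeping gene lists.

    Attributes
    ----------
    ims_genes_ : list of str
        The selected suppression genes.
    discovery_ : DiscoveryResult
        Full per-gene p-value detail.
    cutoff_ : float
        Youden-optimal ratio cutoff learned on the training samples.
    classes_ : ndarray
        ``[0, 1]`` (nonresponder, responder).
    """

    def __init__(self, k_top: int = 18, universe=None, combine: str = "pearson",
                 pseudocount: float = 1.0, input_scale: str = "log2",
                 ifng_genes=IFNG_10, hk_genes=HK_20):
        self.k_top = k_top
        self.universe = universe
        self.combine = combine
        self.pseudocount = pseudocount
        self.input_scale = input_scale
        self.ifng_genes = ifng_genes
        self.hk_genes = hk_genes

    def _ifng_sig(self) -> GeneSignature:
        return GeneSignature("IFNG", tuple(self.ifng_genes), "mean")

    def fit(self, X, y, groups=None):
        """Learn the signature and cutoff.

        Parameters
        ----------
        X : DataFrame (samples x genes) or ExpressionMatrix
        y : array-like of RECIST labels {CR, PR, SD, PD}, one per sample.
        groups : array-like of cohort labels or None
            None treats all samples as a single cohort.
        """
        expr = _as_expression(X, self.input_scale)
        y = np.asarray(y, dtype=object)
        if len(y) != len(expr.sample_ids):
            raise ValueError(f"y has {len(y)} labels for {len(expr.sample_ids)} samples")
        if groups is None:
            groups = np.zeros(len(y), dtype=int)
        groups = np.asarray(groups)

        cohorts = []
        for gname in pd.unique(groups):
            mask = groups == gname
            ids = [s for s, m in zip(expr.sample_ids, mask) if m]
            clinical = ClinicalTable(pd.DataFrame({
                "sample_id": ids, "response": y[mask]}))
            cohorts.append(Cohort(str(gname), expr.subset_samples(ids), clinical))

        if self.universe is None:
            shared = set(expr.gene_ids)
            excluded = set(g.upper() for g in self.ifng_genes) | set(
                g.upper() for g in self.hk_genes)
            universe = sorted(shared - excluded)
        else:
            universe = list(self.universe)

        self.discovery_ = discover_ims(
            cohorts, universe, k_top=self.k_top, ifng_sig=self._ifng_sig(),
            hk_genes=self.hk_genes, pseudocount=self.pseudocount,
            combine=self.combine)
        self.ims_genes_ = list(self.discovery_.selected)
        self.classes_ = np.array([0, 1])

        # training-set ratio scores, pooled across cohorts, set the cutoff
        scores = []
        clin_frames = []
        for cohort in cohorts:
            s = score_ratio_on_cohort(cohort, self.ims_genes_, self._ifng_sig(),
                                      self.hk_genes, self.pseudocount)
            scores.append(s.scores)
            clin_frames.append(cohort.clinical.table)
        from .containers import SignatureScores
        pooled = SignatureScores("IFNG/IMS", pd.concat(scores))
        pooled_clin = ClinicalTable(pd.concat(clin_frames))
        points, self.train_auc_, self.train_auc_ci_ = roc_auc(pooled, pooled_clin)
        self.cutoff_, self.youden_j_ = youden_cutoff(points)
        return self

    def decision_function(self, X) -> np.ndarray:
        """IFN-g/IMS ratio score per sample (higher = more likely responder)."""
        if not hasattr(self, "ims_genes_"):
            raise ValueError("estimator is not fitted; call fit first")
        expr = _as_expression(X, self.input_scale)
        clinical = ClinicalTable(pd.DataFrame({
            "sample_id": expr.sample_ids,
            "response": ["PD"] * len(expr.sample_ids)}))  # labels unused for scoring
        cohort = Cohort("predict", expr, clinical)
        s = score_ratio_on_cohort(cohort, self.ims_genes_, self._ifng_sig(),
                                  self.hk_genes, self.pseudocount)
        return s.scores.to_numpy()

    def predict(self, X) -> np.ndarray:
        """1 = predicted responder (ratio above the learned cutoff)."""
        return (self.decision_function(X) > self.cutoff_).astype(int)
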