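"""Normalization and signature scoring.

The pipeline works on log2 FPKM. Per-sample housekeeping normalization
subtracts the mean log2 expression of 20 stable reference genes from every
gene of that sample. Signature scores are then the arithmetic mean of the
member genes (or a PC1 projection / gene-pair count for comparator
archetypes), and the predictive biomarker is the IFN-g/IMS ratio: the
difference of the two mean scores in the log domain, which cancels any
per-sample additive offset and is therefore self-normalizing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SignatureScores
from .genesets import GeneSignature

logger = logging.getLogger("imsig")


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) on a linear-FPKM matrix.

    Refuses to run twice: the input must carry scale_tag ``linear_fpkm``.
    """
    if m.scale_tag != "linear_fpkm":
        raise ValueError(
            f"log2_transform expects linear_fpkm input, got {m.scale_tag!r} "
            "(double-transform guard)"
        )
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    return ExpressionMatrix(np.log2(m.values + pseudocount), scale_tag="log2")


def housekeeping_normalize(m: ExpressionMatrix, hk_genes) -> ExpressionMatrix:
    """Subtract each sample's mean log2 housekeeping expression from all genes."""
    if m.scale_tag != "log2":
        raise ValueError(f"housekeeping_normalize expects log2 input, got {m.scale_tag!r}")
    present = m.present_genes(hk_genes, context="housekeeping normalization")
    if not present:
        raise ValueError("no housekeeping gene present in the matrix")
    hk_mean = m.values.loc[present].mean(axis=0)  # per sample
    return ExpressionMatrix(m.values.sub(hk_mean, axis=1), scale_tag="log2_hknorm")


def _score_mean(values: pd.DataFrame) -> pd.Series:
    return values.mean(axis=0)


def _score_pc1(values: pd.DataFrame) -> pd.Series:
    if values.shape[1] < 2:
        raise ValueError("pc1 scoring needs at least 2 samples")
    centered = values.sub(values.mean(axis=1), axis=0)  # center genes across samples
    # samples are observations: PC1 of the samples x genes matrix
    u, s, vt = np.linalg.svd(centered.to_numpy().T, full_matrices=False)
    scores = u[:, 0] * s[0]
    gene_mean = values.mean(axis=0).to_numpy()
    # orient so the score tracks the per-sample mean of the signature genes
    if np.dot(scores, gene_mean - gene_mean.mean()) < 0:
        scores = -scores
    return pd.Series(scores, index=values.columns)


def _score_pair_sum(m: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    counts = pd.Series(0.0, index=m.sample_ids)
    used = 0
    genes = set(m.gene_ids)
    for a, b in sig.pairs:
        if a in genes and b in genes:
            counts += (m.values.loc[a] > m.values.loc[b]).astype(float)
            used += 1
    if used == 0:
        raise ValueError(f"signature {sig.name!r}: no pair with both genes present")
    if used < len(sig.pairs):
        logger.warning("signature %s: %d of %d pairs usable (missing genes excluded)",
                       sig.name, used, len(sig.pairs))
    return counts


def score_signature(m: ExpressionMatrix, sig: GeneSignature) -> SignatureScores:
    """Per-sample score of one signature; absent genes are excluded with a warning."""
    if m.scale_tag not in ("log2", "log2_hknorm"):
        raise ValueError(
            f"scoring expects log2 or log2_hknorm input, got {m.scale_tag!r}"
        )
    if sig.method == "pair_sum":
        return SignatureScores(sig.name, _score_pair_sum(m, sig))
    present = m.present_genes(sig.genes, context=f"signature {sig.name}")
    if not present:
        raise ValueError(f"signature {sig.name!r}: no gene present in the matrix")
    sub = m.values.loc[present]
    if sig.method == "mean":
        return SignatureScores(sig.name, _score_mean(sub))
    return SignatureScores(sig.name, _score_pc1(sub))


def ratio_score(ifng: SignatureScores, ims: SignatureScores,
                name: str = "IFNG/IMS") -> SignatureScores:
    """IFN-g minus IMS score per sample (log-domain ratio)."""
    if list(ifng.sample_ids) != list(ims.sample_ids):
        if set(ifng.sample_ids) != set(ims.sample_ids):
            raise ValueError("ratio_score: sample sets differ between the two scores")
        ims = SignatureScores(ims.signature_name, ims.scores.loc[ifng.sample_ids])
    return SignatureScores(name, ifng.scores - ims.scores)
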