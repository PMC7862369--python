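"""Immunosuppression-signature discovery from multi-cohort response data.

For each cohort independently (to avoid cross-dataset batch effects), gene
expression is log2-transformed, housekeeping-normalized, and adjusted by
subtracting the sample's IFN-g signature score; a one-sided pooled-variance
Student's t-test then asks, per gene, whether expression is uplifted in
nonresponders (PD) versus responders (CR/PR), with stable-disease samples
excluded. Per-cohort p-values are combined with Pearson's method — the
left tail of chi-squared on -2*sum(log(1-p_i)) — which is dominated by the
*largest* p-value, so a gene must be consistently significant in every
cohort. Genes are ranked by combined p and the top K (default 18) form
the signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Cohort, ExpressionMatrix, SignatureScores
from .genesets import GeneSignature, HK_20, IFNG_10
from .scoring import housekeeping_normalize, log2_transform, ratio_score, score_signature

logger = logging.getLogger("imsig")

P_CLIP = 1e-15  # keep log(1-p) finite when a cohort yields p = 1


@dataclass
class DiscoveryResult:
    """Per-gene per-cohort p-values, combined p-values and the top-K selection."""

    gene_universe: list[str]
    per_cohort_p: pd.DataFrame = field(repr=False)  # genes x cohorts
    combined_p: pd.Series = field(repr=False)
    ranking: list[str]
    selected: list[str]
    k_cohorts: int

    def as_frame(self) -> pd.DataFrame:
        """Tidy table: gene, per-cohort p columns, combined_p, rank, selected."""
        out = self.per_cohort_p.copy()
        out.columns = [f"p_{c}" for c in out.columns]
        out["combined_p"] = self.combined_p
        out = out.loc[self.ranking]
        out["rank"] = np.arange(1, len(out) + 1)
        out["selected"] = out.index.isin(self.selected)
        out.index.name = "gene"
        return out


def adjust_by_ifng(m: ExpressionMatrix, ifng: SignatureScores) -> ExpressionMatrix:
    """Subtract each sample's IFN-g score from all of its gene values."""
    if m.scale_tag != "log2_hknorm":
        raise ValueError(f"adjust_by_ifng expects log2_hknorm input, got {m.scale_tag!r}")
    if set(m.sample_ids) != set(ifng.sample_ids):
        raise ValueError("adjust_by_ifng: sample sets differ between matrix and scores")
    adj = m.values.sub(ifng.scores.loc[m.sample_ids], axis=1)
    return ExpressionMatrix(adj, scale_tag="log2_hknorm_ifngadj")


def one_sided_ttest_per_gene(cohort: Cohort, universe,
                             matrix: ExpressionMatrix | None = None) -> pd.Series:
    """Upper-tail pooled-variance t-test of mean(PD) - mean(CR/PR) per gene.

    Small p means the gene is uplifted in nonresponders. SD samples are
    excluded. Zero-pooled-variance genes get p = 0.5 when the group means
    are equal, else 0 or 1 by the sign of the difference.

    ``matrix`` overrides ``cohort.expression`` so callers can pass an
    already-adjusted matrix while keeping the cohort's clinical labels.
    """
    m = matrix if matrix is not None else cohort.expression
    resp = cohort.clinical.response
    pd_ids = [s for s in resp.index[resp == "PD"] if s in set(m.sample_ids)]
    r_ids = [s for s in resp.index[resp.isin(["CR", "PR"])] if s in set(m.sample_ids)]
    if len(pd_ids) < 2 or len(r_ids) < 2:
        raise ValueError(
            f"cohort {cohort.name!r}: need >= 2 samples per arm, "
            f"got {len(pd_ids)} PD and {len(r_ids)} CR/PR"
        )
    genes = [g for g in universe if g in set(m.gene_ids)]
    missing = [g for g in universe if g not in set(m.gene_ids)]
    if missing:
        logger.warning("cohort %s: %d universe gene(s) absent, dropped: %s",
                       cohort.name, len(missing), ", ".join(sorted(missing)))
    if not genes:
        raise ValueError(f"cohort {cohort.name!r}: no universe gene present")

    x_pd = m.values.loc[genes, pd_ids].to_numpy()
    x_r = m.values.loc[genes, r_ids].to_numpy()
    n1, n2 = x_pd.shape[1], x_r.shape[1]
    df = n1 + n2 - 2
    m1, m2 = x_pd.mean(axis=1), x_r.mean(axis=1)
    s1 = x_pd.var(axis=1, ddof=1)
    s2 = x_r.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = stats.t.sf(t, df)
    degenerate = sp2 == 0
    if degenerate.any():
        p = np.where(degenerate & (diff == 0), 0.5, p)
        p = np.where(degenerate & (diff > 0), 0.0, p)
        p = np.where(degenerate & (diff < 0), 1.0, p)
    return pd.Series(p, index=genes, name=cohort.name)


def pearson_combine(p_values) -> float:
    """Combine k p-values with Pearson's method.

    X = -2 * sum(log(1 - p_i)); combined p = P(chi2_{2k} <= X), the *left*
    tail, so the combination is significant only when every p_i is small.
    Reduces to the identity at k = 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("pearson_combine: empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("pearson_combine: p-values must lie in [0, 1]")
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    x = -2.0 * np.sum(np.log1p(-p))
    return float(stats.chi2.cdf(x, 2 * p.size))


def fisher_combine(p_values) -> float:
    """Fisher's method (right tail of chi2 on -2*sum(log p)); comparison only."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine: empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("fisher_combine: p-values must lie in [0, 1]")
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, 2 * p.size))


_COMBINERS = {"pearson": pearson_combine, "fisher": fisher_combine}


def prepare_cohort_matrix(cohort: Cohort, ifng_sig: GeneSignature | None = None,
                          hk_genes=HK_20, pseudocount: float = 1.0,
                          adjust: bool = True) -> ExpressionMatrix:
    """log2 -> housekeeping-normalize -> (optionally) IFN-g-adjust one cohort.

    Only samples with clinical rows are retained. Matrices already on log2
    scale skip the transform; already-normalized tags skip normalization.
    """
    if ifng_sig is None:
        ifng_sig = GeneSignature("IFNG_10", IFNG_10, "mean")
    m = cohort.expression.subset_samples(cohort.clinical.sample_ids)
    if m.scale_tag == "linear_fpkm":
        m = log2_transform(m, pseudocount)
    if m.scale_tag == "log2":
        m = housekeeping_normalize(m, hk_genes)
    if not adjust:
        return m
    if m.scale_tag == "log2_hknorm":
        ifng = score_signature(m, ifng_sig)
        m = adjust_by_ifng(m, ifng)
    return m


def discover_ims(cohorts: list[Cohort], universe, k_top: int = 18,
                 ifng_sig: GeneSignature | None = None, hk_genes=HK_20,
                 pseudocount: float = 1.0, combine: str = "pearson",
                 prepared: dict[str, ExpressionMatrix] | None = None) -> DiscoveryResult:
    """Run the full discovery pipeline over one or more cohorts.

    Each cohort is processed independently; combined p-values are defined
    only for genes present in every cohort; ranking breaks ties
    lexicographically by gene symbol; ``selected`` is the first ``k_top``.

    ``prepared`` optionally maps cohort name -> pre-adjusted matrix, letting
    repeated discovery runs (e.g. the leave-datasets-out test) skip the
    normalization pipeline.
    """
    if not cohorts:
        raise ValueError("discover_ims: need at least one cohort")
    if combine not in _COMBINERS:
        raise ValueError(f"unknown combine method {combine!r}")
    universe = [str(g).upper() for g in universe]

    per_cohort = {}
    for cohort in cohorts:
        if prepared is not None and cohort.name in prepared:
            m = prepared[cohort.name]
        else:
            m = prepare_cohort_matrix(cohort, ifng_sig, hk_genes, pseudocount)
        per_cohort[cohort.name] = one_sided_ttest_per_gene(cohort, universe, matrix=m)

    pmat = pd.DataFrame(per_cohort)  # genes x cohorts; NaN where gene absent
    surviving = pmat.dropna().index.tolist()
    dropped = sorted(set(universe) - set(surviving))
    if dropped:
        logger.warning("discovery: %d universe gene(s) absent from >= 1 cohort, dropped",
                       len(dropped))
    if not surviving:
        raise ValueError("discover_ims: no universe gene present in every cohort")
    pmat = pmat.loc[surviving]

    combiner = _COMBINERS[combine]
    combined = pmat.apply(lambda row: combiner(row.to_numpy()), axis=1)
    order = sorted(surviving, key=lambda g: (combined[g], g))
    if k_top > len(order):
        logger.warning("discovery: k_top=%d exceeds universe size %d; selecting all",
                       k_top, len(order))
    selected = order[:min(k_top, len(order))]
    return DiscoveryResult(
        gene_universe=surviving,
        per_cohort_p=pmat,
        combined_p=combined,
        ranking=order,
        selected=selected,
        k_cohorts=len(cohorts),
    )


def score_ratio_on_cohort(cohort: Cohort, ims_genes,
                          ifng_sig: GeneSignature | None = None, hk_genes=HK_20,
                          pseudocount: float = 1.0,
                          prepared_hknorm: ExpressionMatrix | None = None) -> SignatureScores:
    """IFN-g/IMS ratio scores for one cohort's clinical samples."""
    if ifng_sig is None:
        ifng_sig = GeneSignature("IFNG_10", IFNG_10, "mean")
    m = prepared_hknorm if prepared_hknorm is not None else prepare_cohort_matrix(
        cohort, ifng_sig, hk_genes, pseudocount, adjust=False)
    ims_sig = GeneSignature("IMS", tuple(ims_genes), "mean")
    ifng = score_signature(m, ifng_sig)
    ims = score_signature(m, ims_sig)
    return ratio_score(ifng, ims)
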