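"""Leave-datasets-out robustness testing of signature discovery.

Every 3-of-n split of the cohort collection (35 splits for 7 cohorts) is
used once: the immunosuppression signature is rediscovered on the three
discovery cohorts and the IFN-g/IMS ratio plus any comparator signatures
are evaluated (SD-excluded AUC) on each held-out cohort. Gene occurrence
frequencies across the per-split signatures measure the stability of the
selection, and a Wilcoxon matched-pairs signed rank test compares the
ratio's per-split AUC with a comparator's.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Cohort, SignatureScores
from .discovery import (discover_ims, prepare_cohort_matrix, score_ratio_on_cohort)
from .evaluation import _labels_crpr_vs_pd, auc_concordance
from .genesets import GeneSignature, HK_20, IFNG_10
from .scoring import score_signature

logger = logging.getLogger("imsig")

RATIO_METHOD = "IFNG/IMS"


def enumerate_splits(cohort_names: list[str], n_discovery: int = 3,
                     max_splits: int | None = None, seed: int | None = None):
    """All C(n, n_discovery) (discovery, validation) splits, lexicographic.

    ``max_splits`` optionally subsamples the enumeration (seeded) for large
    cohort collections; the default is the complete deterministic list.
    """
    names = list(cohort_names)
    if n_discovery >= len(names):
        raise ValueError(
            f"n_discovery={n_discovery} must be smaller than the number of "
            f"cohorts ({len(names)})"
        )
    splits = []
    for disc in itertools.combinations(names, n_discovery):
        valid = tuple(n for n in names if n not in disc)
        splits.append((disc, valid))
    if max_splits is not None and max_splits < len(splits):
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(splits), size=max_splits, replace=False))
        splits = [splits[i] for i in idx]
    return splits


def wilcoxon_signed_rank(paired_a, paired_b, exact_max_n: int = 20) -> float:
    """Two-sided Wilcoxon matched-pairs signed rank p-value.

    Zero differences are dropped (Wilcoxon convention); ties among absolute
    differences get average ranks. Exact null distribution by dynamic
    programming over sign assignments for n <= ``exact_max_n``, else the
    normal approximation with continuity correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("wilcoxon_signed_rank requires at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        logger.warning("wilcoxon_signed_rank: all differences zero; p = 1")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    n = d.size
    if n <= exact_max_n:
        # doubled ranks are integers even with .5 average ranks
        r2 = np.round(ranks * 2).astype(int)
        total = r2.sum()
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[:-r] if r > 0 else dist
            dist = dist + shifted
        dist /= 2.0 ** n
        w2 = int(round(w_pos * 2))
        lower = dist[: w2 + 1].sum()
        upper = dist[w2:].sum()
        return float(min(1.0, 2.0 * min(lower, upper)))
    mu = n * (n + 1) / 4.0
    tie_counts = Counter(ranks.tolist()).values()
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - sum(t ** 3 - t for t in tie_counts) / 48.0
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / math.sqrt(sigma2)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class RobustnessResult:
    """Outcome of the leave-datasets-out randomized test."""

    splits: list[tuple[tuple, tuple]]
    per_split_signature: list[list[str]] = field(repr=False)
    per_split_auc: pd.DataFrame = field(repr=False)  # columns: split, method, cohort, auc
    gene_frequency: Counter = field(repr=False)
    skipped_splits: list[tuple] = field(default_factory=list)
    wilcoxon_p: float | None = None
    compared_method: str | None = None

    def method_summary(self, aggregate: str = "per_split_median") -> pd.DataFrame:
        """Per-method AUC summary over splits.

        ``per_split_median`` (default): median AUC over validation cohorts
        within each split, then summarized over splits. ``pooled``: all
        (split x cohort) AUCs pooled.
        """
        if aggregate == "per_split_median":
            per_split = (self.per_split_auc
                         .groupby(["method", "split"])["auc"].median()
                         .reset_index())
            grp = per_split.groupby("method")["auc"]
        elif aggregate == "pooled":
            grp = self.per_split_auc.groupby("method")["auc"]
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
        return grp.agg(["median", "mean", "min", "max", "count"])

    def per_split_median_auc(self, method: str) -> pd.Series:
        sub = self.per_split_auc[self.per_split_auc["method"] == method]
        return sub.groupby("split")["auc"].median()


def run_randomized_test(cohorts: list[Cohort], universe,
                        comparators: list[GeneSignature] | None = None,
                        k_top: int = 18, n_discovery: int = 3,
                        ifng_sig: GeneSignature | None = None, hk_genes=HK_20,
                        pseudocount: float = 1.0, combine: str = "pearson",
                        compare_to: str | None = None,
                        max_splits: int | None = None,
                        seed: int | None = None) -> RobustnessResult:
    """Rediscover the signature on every discovery triple, score the rest.

    ``comparators`` are fixed signatures scored alongside the rediscovered
    IFN-g/IMS ratio; ``compare_to`` names the comparator for the Wilcoxon
    matched-pairs comparison of per-split median AUCs (defaults to the first
    comparator when any exist). Splits whose discovery cohorts fail the
    t-test preconditions are skipped with a logged warning and recorded.
    """
    if ifng_sig is None:
        ifng_sig = GeneSignature("IFNG_10", IFNG_10, "mean")
    if comparators is None:
        comparators = [ifng_sig]
    by_name = {c.name: c for c in cohorts}
    splits = enumerate_splits([c.name for c in cohorts], n_discovery,
                              max_splits=max_splits, seed=seed)

    # normalization does not depend on the split: prepare each cohort once
    prepared_adj = {c.name: prepare_cohort_matrix(c, ifng_sig, hk_genes, pseudocount)
                    for c in cohorts}
    prepared_hk = {c.name: prepare_cohort_matrix(c, ifng_sig, hk_genes, pseudocount,
                                                 adjust=False)
                   for c in cohorts}
    comparator_scores = {
        (sig.name, c.name): score_signature(prepared_hk[c.name], sig)
        for sig in comparators for c in cohorts
    }

    rows = []
    signatures = []
    kept_splits = []
    skipped = []
    freq: Counter = Counter()
    for disc, valid in splits:
        try:
            result = discover_ims([by_name[n] for n in disc], universe, k_top,
                                  ifng_sig, hk_genes, pseudocount, combine,
                                  prepared=prepared_adj)
        except ValueError as exc:
            logger.warning("split %s skipped: %s", disc, exc)
            skipped.append((disc, valid))
            continue
        kept_splits.append((disc, valid))
        signatures.append(list(result.selected))
        freq.update(result.selected)
        split_id = "+".join(disc)
        for vname in valid:
            cohort = by_name[vname]
            resp = cohort.clinical.response
            if not (resp.isin(["CR", "PR"]).any() and (resp == "PD").any()):
                logger.warning("split %s: validation cohort %s lacks both "
                               "response classes; AUC skipped", disc, vname)
                continue
            ratio = score_ratio_on_cohort(cohort, result.selected, ifng_sig,
                                          hk_genes, pseudocount,
                                          prepared_hknorm=prepared_hk[vname])
            methods = {RATIO_METHOD: ratio}
            for sig in comparators:
                methods[sig.name] = comparator_scores[(sig.name, vname)]
            for mname, sc in methods.items():
                x, y = _labels_crpr_vs_pd(sc, cohort.clinical)
                rows.append({"split": split_id, "method": mname, "cohort": vname,
                             "auc": auc_concordance(x, y)})

    per_split_auc = pd.DataFrame(rows, columns=["split", "method", "cohort", "auc"])
    result = RobustnessResult(kept_splits, signatures, per_split_auc, freq,
                              skipped_splits=skipped)
    if compare_to is None and comparators:
        compare_to = comparators[0].name
    if compare_to is not None and len(kept_splits) >= 5:
        a = result.per_split_median_auc(RATIO_METHOD)
        b = result.per_split_median_auc(compare_to).loc[a.index]
        result.wilcoxon_p = wilcoxon_signed_rank(a.to_numpy(), b.to_numpy())
        result.compared_method = compare_to
    return result


def gene_frequency_table(result: RobustnessResult) -> pd.DataFrame:
    """Gene occurrence counts across per-split signatures, descending."""
    items = sorted(result.gene_frequency.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(items, columns=["gene", "count"])
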