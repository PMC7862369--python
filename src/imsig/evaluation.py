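"""Response-prediction and survival evaluation of per-sample scores.

AUC follows the Mann-Whitney concordance definition (ties count 1/2) with
stable-disease patients excluded; its confidence interval uses DeLong's
variance estimate by default or a stratified bootstrap. The classification
cutoff maximizes the Youden index J = sensitivity + specificity - 1 and is
placed at the midpoint between the bracketing distinct scores. Contingency
analysis uses the two-sided Fisher exact test (hypergeometric enumeration);
group score comparisons use the two-tailed Mann-Whitney U-test (exact by
enumeration at small n). Survival stratification uses Kaplan-Meier curves,
the log-rank test and a single-covariate proportional-hazards model.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClinicalTable, SignatureScores

logger = logging.getLogger("imsig")


# --------------------------------------------------------------------------
# ROC / AUC

@dataclass
class RocPoint:
    fpr: float
    tpr: float
    threshold: float


def _labels_crpr_vs_pd(scores: SignatureScores, clinical: ClinicalTable):
    """Align scores with CR/PR(=1) vs PD(=0) labels, SD excluded."""
    resp = clinical.response
    keep = [s for s in scores.sample_ids if s in resp.index and resp[s] != "SD"]
    y = np.array([1 if resp[s] in ("CR", "PR") else 0 for s in keep])
    x = scores.scores.loc[keep].to_numpy()
    return x, y


def auc_concordance(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5*P(tie)."""
    pos = x[y == 1]
    neg = x[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _delong_variance(x: np.ndarray, y: np.ndarray) -> float:
    """DeLong structural-component variance of the AUC estimate."""
    pos = x[y == 1]
    neg = x[y == 0]
    m, n = pos.size, neg.size
    # placement values: V10_i = P(pos_i > neg) + 0.5 P(tie), analogously V01
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores: SignatureScores, clinical: ClinicalTable,
            positive_def: str = "crpr_vs_pd", ci_method: str = "delong",
            n_boot: int = 2000, seed: int = 0):
    """ROC points, AUC and 95% CI for CR/PR vs PD (SD excluded).

    Returns ``(roc_points, auc, (lo, hi))``. ROC points are computed at every
    distinct observed score plus -inf/+inf sentinels, with "predicted
    responder" meaning score strictly greater than the threshold.
    """
    if positive_def != "crpr_vs_pd":
        raise ValueError(f"unknown positive definition {positive_def!r}")
    x, y = _labels_crpr_vs_pd(scores, clinical)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("roc_auc: need at least one CR/PR and one PD sample")
    pos, neg = x[y == 1], x[y == 0]
    thresholds = np.concatenate([[-np.inf], np.unique(x), [np.inf]])
    points = [RocPoint(fpr=float(np.mean(neg > t)), tpr=float(np.mean(pos > t)),
                       threshold=float(t)) for t in thresholds]
    auc = auc_concordance(x, y)
    if ci_method == "delong":
        se = np.sqrt(_delong_variance(x, y))
        z = stats.norm.ppf(0.975)
        ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        aucs = []
        for _ in range(n_boot):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            bx = np.concatenate([bp, bn])
            by = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
            aucs.append(auc_concordance(bx, by))
        ci = tuple(np.quantile(aucs, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return points, auc, ci


def youden_cutoff(roc_points: list[RocPoint]) -> tuple[float, float]:
    """Cutoff maximizing J = TPR - FPR, at the midpoint of the bracketing scores.

    Ties in J resolve toward the lower cutoff (larger predicted-responder
    group). The -inf sentinel maps to a cutoff one unit below the smallest
    score; the +inf sentinel to one unit above the largest.
    """
    if not roc_points:
        raise ValueError("youden_cutoff: empty ROC")
    finite = sorted({p.threshold for p in roc_points if np.isfinite(p.threshold)})
    if not finite:
        raise ValueError("youden_cutoff: no finite thresholds")

    def as_cutoff(t: float) -> float:
        if t == -np.inf:
            return finite[0] - 1.0
        if t == np.inf:
            return finite[-1] + 1.0
        i = finite.index(t)
        return (t + finite[i + 1]) / 2.0 if i + 1 < len(finite) else t + 1.0

    best = None
    for p in roc_points:
        j = p.tpr - p.fpr
        c = as_cutoff(p.threshold)
        if best is None or j > best[1] + 1e-12 or (abs(j - best[1]) <= 1e-12 and c < best[0]):
            best = (c, j)
    return best


# --------------------------------------------------------------------------
# Contingency analysis

def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p by enumerating tables with fixed margins.

    Sums the hypergeometric probabilities of every table at most as likely
    as the observed one (within a small relative slack for float safety).
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    row1, col1, n = a + b, a + c, a + b + c + d
    if n == 0:
        raise ValueError("empty contingency table")
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def classify_and_tabulate(scores: SignatureScores, cutoff: float,
                          clinical: ClinicalTable,
                          responder_def: str = "disease_control"):
    """Dichotomize at ``cutoff`` (predicted responder <=> score > cutoff).

    ``responder_def`` decides the *actual* responder label: ``crpr`` excludes
    SD patients; ``disease_control`` counts SD as clinical benefit. Returns
    ``(confusion, accuracy_by_group, fisher_p)`` where confusion is a 2x2
    DataFrame predicted x actual and accuracy_by_group gives the fraction of
    correct calls within each predicted group.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    actual = clinical.responders(responder_def)
    keep = [s for s in scores.sample_ids if s in actual.index]
    if not keep:
        raise ValueError("no sample left after responder-definition filtering")
    actual = actual.loc[keep]
    predicted = scores.scores.loc[keep] > cutoff

    confusion = pd.DataFrame(
        [[int((predicted & actual).sum()), int((predicted & ~actual).sum())],
         [int((~predicted & actual).sum()), int((~predicted & ~actual).sum())]],
        index=["pred_responder", "pred_nonresponder"],
        columns=["actual_responder", "actual_nonresponder"],
    )
    acc = {}
    n_pred_r = confusion.loc["pred_responder"].sum()
    n_pred_nr = confusion.loc["pred_nonresponder"].sum()
    acc["pred_responder"] = (
        confusion.loc["pred_responder", "actual_responder"] / n_pred_r
        if n_pred_r else np.nan)
    acc["pred_nonresponder"] = (
        confusion.loc["pred_nonresponder", "actual_nonresponder"] / n_pred_nr
        if n_pred_nr else np.nan)
    fisher_p = fisher_exact_two_sided(confusion.to_numpy())
    return confusion, acc, fisher_p


# --------------------------------------------------------------------------
# Group comparison

def mannwhitney_two_sided(group_a, group_b, exact_max_n: int = 12) -> float:
    """Two-tailed Mann-Whitney U p-value.

    Exact by full enumeration of group assignments when the combined sample
    size is <= ``exact_max_n`` (handles ties correctly); otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        us = []
        for idx in itertools.combinations(range(n1 + n2), n1):
            us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0)
        us = np.asarray(us)
        lower = np.mean(us <= u_obs + 1e-9)
        upper = np.mean(us >= u_obs - 1e-9)
        return float(min(1.0, 2.0 * min(lower, upper)))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def compare_scores_between_groups(scores: SignatureScores, groups: pd.Series) -> float:
    """Two-tailed Mann-Whitney p comparing scores between two labeled groups."""
    groups = groups.loc[[s for s in scores.sample_ids if s in groups.index]]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    x = scores.scores.loc[groups.index]
    return mannwhitney_two_sided(x[groups == levels[0]], x[groups == levels[1]])


# --------------------------------------------------------------------------
# Survival

def _survival_frame(clinical: ClinicalTable, group_labels: pd.Series) -> pd.DataFrame:
    if not clinical.has_survival:
        raise ValueError("clinical table lacks os_time/os_event columns")
    ids = [s for s in clinical.sample_ids if s in group_labels.index]
    df = clinical.table.loc[ids, ["os_time", "os_event"]].copy()
    df["group"] = group_labels.loc[ids]
    if df["group"].nunique() != 2:
        raise ValueError("survival comparison needs exactly 2 groups")
    return df


def km_logrank(clinical: ClinicalTable, group_labels: pd.Series):
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    Returns ``(km_curves, chi2, p)`` with ``km_curves`` a dict
    group -> DataFrame(timeline, survival probability).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    df = _survival_frame(clinical, group_labels)
    curves = {}
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_time"], sub["os_event"], label=str(g))
        curves[g] = kmf.survival_function_
    g0, g1 = sorted(df["group"].unique())
    a, b = df[df["group"] == g0], df[df["group"] == g1]
    res = logrank_test(a["os_time"], b["os_time"], a["os_event"], b["os_event"])
    return curves, float(res.test_statistic), float(res.p_value)


def hazard_ratio_two_group(clinical: ClinicalTable, group_labels: pd.Series):
    """HR (group=1 vs group=0) from a single-covariate Cox model (Efron ties).

    Returns ``(hr, (lo, hi), unbounded)`` where ``unbounded`` flags complete
    separation / non-identified fits with an effectively infinite CI.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = _survival_frame(clinical, group_labels)
    if df["os_event"].sum() == 0:
        raise ValueError("hazard ratio requires at least one event")
    g0, g1 = sorted(df["group"].unique())
    df = df.assign(group=(df["group"] == g1).astype(float))
    cph = CoxPHFitter()
    unbounded = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="os_time", event_col="os_event")
        except ConvergenceError:
            logger.warning("hazard_ratio: complete separation; refitting with small ridge")
            unbounded = True
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="os_time", event_col="os_event")
        if any("did not converge" in str(w.message).lower()
               or "complete separation" in str(w.message).lower() for w in caught):
            unbounded = True
    with np.errstate(over="ignore"):
        hr = float(np.exp(cph.params_["group"]))
        lo = float(np.exp(cph.confidence_intervals_.iloc[0, 0]))
        hi = float(np.exp(cph.confidence_intervals_.iloc[0, 1]))
    if unbounded:
        logger.warning("hazard_ratio: CI should be treated as unbounded")
    return hr, (lo, hi), unbounded


# --------------------------------------------------------------------------
# Aggregate report

@dataclass
class EvaluationResult:
    """Full evaluation of one score against one clinical table."""

    roc_points: list[RocPoint] = field(repr=False)
    auc: float
    auc_ci: tuple[float, float]
    youden_cutoff: float
    youden_J: float
    confusion: pd.DataFrame = field(repr=False)
    accuracy_by_group: dict
    fisher_p: float
    mannwhitney_p: float
    logrank_p: float | None = None
    logrank_chi2: float | None = None
    hazard_ratio: float | None = None
    hr_ci: tuple[float, float] | None = None


def evaluate_scores(scores: SignatureScores, clinical: ClinicalTable,
                    responder_def: str = "disease_control",
                    cutoff: float | None = None,
                    ci_method: str = "delong", seed: int = 0) -> EvaluationResult:
    """One-stop evaluation: ROC/AUC, Youden cutoff, confusion, survival.

    ``cutoff=None`` selects the Youden-optimal cutoff from the SD-excluded
    ROC; survival statistics are included when the clinical table carries
    os_time/os_event (groups split at the cutoff).
    """
    points, auc, ci = roc_auc(scores, clinical, ci_method=ci_method, seed=seed)
    yc, j = youden_cutoff(points)
    if cutoff is None:
        cutoff = yc
    confusion, acc, fisher_p = classify_and_tabulate(scores, cutoff, clinical,
                                                     responder_def)
    x, y = _labels_crpr_vs_pd(scores, clinical)
    mw_p = mannwhitney_two_sided(x[y == 1], x[y == 0])
    result = EvaluationResult(points, auc, ci, yc, j, confusion, acc, fisher_p, mw_p)
    if clinical.has_survival:
        labels = (scores.scores > cutoff).map({True: "high", False: "low"})
        labels = labels.loc[[s for s in labels.index if s in set(clinical.sample_ids)]]
        try:
            _, chi2, p = km_logrank(clinical, labels)
            result.logrank_p = p
            result.logrank_chi2 = chi2
            hr, hr_ci, _ = hazard_ratio_two_group(clinical, labels)
            result.hazard_ratio = hr
            result.hr_ci = hr_ci
        except ValueError as exc:
            logger.warning("survival evaluation skipped: %s", exc)
    return result
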