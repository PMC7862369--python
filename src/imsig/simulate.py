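"""Seeded multi-cohort synthetic data with planted ground truth.

The generator emulates the statistical structure the discovery pipeline
assumes: each patient carries a latent inflammation factor ``a`` (loading on
the 10 IFN-g genes) and a correlated latent suppression factor ``b``
(loading on the planted suppression genes, which also receive a weak
inflammation loading to induce the positive score correlation seen between
the two signatures). Housekeeping genes are near-constant; every cohort adds
its own per-gene batch offset, recreating the cross-dataset artifact that
per-cohort testing plus Pearson combination is meant to survive. Clinical
benefit ``u = b0 + ba*a - bb*b + eps`` drives both the RECIST label (PD /
SD / PR / CR by ordered thresholds) and exponential survival with log-hazard
``g0 - g1*u`` under administrative censoring.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ClinicalTable, Cohort, ExpressionMatrix
from .genesets import HK_20, IFNG_10
from .io import write_clinical_table, write_expression_matrix


@dataclass
class SyntheticConfig:
    """Generator settings; defaults describe the study-scale conditions.

    The 770-gene universe echoes the size of a curated cancer-immune panel;
    three cohorts of 40 patients approximate the discovery collection.
    Response-model and survival defaults were chosen once to yield a
    realistic ICI-melanoma outcome mix (~64% PD, ~11% SD, ~25% CR+PR).
    """

    n_cohorts: int = 3
    n_per_cohort: int = 40
    n_genes_universe: int = 770
    n_planted_ims: int = 18
    loading_inflammation: float = 1.0     # lambda_A on IFN-g genes
    loading_suppression: float = 1.0      # lambda_B on planted genes
    planted_inflammation_frac: float = 0.3  # lambda_A share given to planted genes
    factor_correlation: float = 0.5       # rho between a and b
    noise_sd: float = 1.0                 # per-gene log2 residual sd
    batch_sd: float = 0.5                 # per-cohort per-gene offset sd
    beta0: float = 0.0                    # latent-benefit intercept
    beta_a: float = 1.0                   # inflammation -> benefit
    beta_b: float = 1.0                   # suppression -> harm
    benefit_noise_sd: float = 0.5
    # PD|SD and SD|response cutpoints, in z-score units of the latent benefit
    # (standardized by its analytic sd), so the marginal response mix stays
    # ~64% PD / 13% SD / 23% CR+PR for any coefficient setting
    recist_thresholds: tuple[float, float] = (0.36, 0.75)
    cr_threshold_offset: float = 1.2      # CR above recist_thresholds[1] + offset
    gamma0: float = -3.0                  # baseline log-hazard (per month)
    gamma1: float = 0.5                   # benefit -> lower hazard
    censor_time: float = 36.0             # months, administrative
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cohort < 8:
            raise ValueError("n_per_cohort must be >= 8 (>= 2 per response arm needed)")
        if not -1.0 <= self.factor_correlation <= 1.0:
            raise ValueError("factor_correlation must lie in [-1, 1]")
        for name in ("loading_inflammation", "loading_suppression", "noise_sd",
                     "batch_sd", "benefit_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        t1, t2 = self.recist_thresholds
        if not t1 < t2:
            raise ValueError("recist_thresholds must be strictly increasing")
        n_special = len(IFNG_10) + self.n_planted_ims
        if self.n_genes_universe < n_special:
            raise ValueError(f"universe must hold at least {n_special} genes")


@dataclass
class PlantedTruth:
    """Ground truth behind one generated collection."""

    planted_genes: list[str]
    universe: list[str]
    factors: pd.DataFrame = field(repr=False)  # sample_id x (cohort, a, b, u)
    config: SyntheticConfig = field(repr=False, default=None)


def _universe_genes(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    """Candidate universe (IFN-g + planted + background) and the planted list.

    The housekeeping genes are present in every generated matrix but sit
    outside the candidate universe: normalization reference genes belong to
    a separate panel class and are never signature candidates.
    """
    planted = [f"SUP{i + 1:03d}" for i in range(cfg.n_planted_ims)]
    n_bg = cfg.n_genes_universe - len(IFNG_10) - cfg.n_planted_ims
    background = [f"BG{i + 1:04d}" for i in range(n_bg)]
    universe = list(IFNG_10) + planted + background
    return universe, planted


def generate_cohorts(cfg: SyntheticConfig) -> tuple[list[Cohort], PlantedTruth]:
    """Generate ``cfg.n_cohorts`` cohorts with planted suppression genes.

    Expression is produced directly on the log2-FPKM scale,
    ``x_gs = mu_g + lA_g*a_s + lB_g*b_s + batch_cg + noise``, with
    ``mu_g ~ N(5, 2^2)`` shared across cohorts and batch offsets redrawn
    per cohort. Matrices carry scale_tag ``log2``.
    """
    rng = np.random.default_rng(cfg.seed)
    universe, planted = _universe_genes(cfg)
    all_genes = universe + list(HK_20)
    g = len(all_genes)
    mu = rng.normal(5.0, 2.0, size=g)

    lam_a = np.zeros(g)
    lam_b = np.zeros(g)
    noise_scale = np.full(g, cfg.noise_sd)
    gene_pos = {gene: i for i, gene in enumerate(all_genes)}
    for gene in IFNG_10:
        lam_a[gene_pos[gene]] = cfg.loading_inflammation
    for gene in planted:
        lam_b[gene_pos[gene]] = cfg.loading_suppression
        lam_a[gene_pos[gene]] = cfg.loading_inflammation * cfg.planted_inflammation_frac
    for gene in HK_20:
        noise_scale[gene_pos[gene]] = cfg.noise_sd / 5.0

    cov = np.array([[1.0, cfg.factor_correlation], [cfg.factor_correlation, 1.0]])
    t_pd, t_sd = cfg.recist_thresholds
    t_cr = t_sd + cfg.cr_threshold_offset

    cohorts = []
    factor_rows = []
    for c in range(cfg.n_cohorts):
        cname = f"cohort{c + 1}"
        batch = rng.normal(0.0, cfg.batch_sd, size=g)
        ab = rng.multivariate_normal([0.0, 0.0], cov, size=cfg.n_per_cohort)
        a_s, b_s = ab[:, 0], ab[:, 1]
        noise = rng.normal(0.0, 1.0, size=(g, cfg.n_per_cohort)) * noise_scale[:, None]
        x = (mu[:, None] + np.outer(lam_a, a_s) + np.outer(lam_b, b_s)
             + batch[:, None] + noise)
        sample_ids = [f"{cname}_s{i + 1:03d}" for i in range(cfg.n_per_cohort)]
        expr = ExpressionMatrix(pd.DataFrame(x, index=all_genes, columns=sample_ids),
                                scale_tag="log2")

        eps = rng.normal(0.0, cfg.benefit_noise_sd, size=cfg.n_per_cohort)
        u = cfg.beta0 + cfg.beta_a * a_s - cfg.beta_b * b_s + eps
        var_u = (cfg.beta_a ** 2 + cfg.beta_b ** 2
                 - 2.0 * cfg.beta_a * cfg.beta_b * cfg.factor_correlation
                 + cfg.benefit_noise_sd ** 2)
        z = (u - cfg.beta0) / (np.sqrt(var_u) if var_u > 0 else 1.0)
        response = np.where(z < t_pd, "PD",
                            np.where(z < t_sd, "SD",
                                     np.where(z < t_cr, "PR", "CR")))
        hazard = np.exp(cfg.gamma0 - cfg.gamma1 * u)
        raw_time = rng.exponential(1.0 / hazard)
        os_time = np.minimum(raw_time, cfg.censor_time)
        os_event = (raw_time <= cfg.censor_time).astype(int)
        clinical = ClinicalTable(pd.DataFrame({
            "sample_id": sample_ids,
            "response": response,
            "os_time": np.round(os_time, 4),
            "os_event": os_event,
            "cohort": cname,
        }))
        cohorts.append(Cohort(cname, expr, clinical))
        for i, sid in enumerate(sample_ids):
            factor_rows.append({"sample_id": sid, "cohort": cname,
                                "a": a_s[i], "b": b_s[i], "u": u[i]})

    factors = pd.DataFrame(factor_rows).set_index("sample_id")
    truth = PlantedTruth(planted_genes=planted, universe=universe,
                         factors=factors, config=cfg)
    return cohorts, truth


def write_fixture_bundle(cfg: SyntheticConfig, out_dir: str) -> dict:
    """Generate and write one bundle: expression + clinical TSV per cohort,
    plus a ground-truth JSON. Files round-trip through the package readers."""
    cohorts, truth = generate_cohorts(cfg)
    os.makedirs(out_dir, exist_ok=True)
    paths = {"expression": [], "clinical": []}
    for cohort in cohorts:
        e = os.path.join(out_dir, f"{cohort.name}_expression.tsv")
        c = os.path.join(out_dir, f"{cohort.name}_clinical.tsv")
        write_expression_matrix(cohort.expression, e)
        write_clinical_table(cohort.clinical, c)
        paths["expression"].append(e)
        paths["clinical"].append(c)
    tpath = os.path.join(out_dir, "truth.json")
    with open(tpath, "w") as fh:
        json.dump({
            "planted_genes": truth.planted_genes,
            "universe": truth.universe,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(truth.config).items()},
        }, fh, indent=1)
    paths["truth"] = tpath
    return paths
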