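"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q quantifies heterogeneity of per-SNP Wald ratios around the
fixed-effects IVW estimate and is referred to a chi-square with J - 1 degrees
of freedom; heterogeneity is conventionally flagged at p < 0.05.

MR-PRESSO detects horizontal-pleiotropy outliers from a simulation-calibrated
residual sum of squares: each SNP's residual is taken against the
leave-one-out IVW prediction, standardized by its outcome SE so the RSS is
scale-free, and compared with the RSS distribution under a parametric
no-pleiotropy model. Per-SNP empirical p-values are Bonferroni-adjusted;
flagged outliers are removed and the IVW estimate recomputed. A distortion
test compares the shift from outlier removal with shifts from random subsets
of the same size. Empirical p-values use the add-one rule and are never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateCorrectionError, InsufficientInstrumentsError
from .estimators import EggerExtra, MrResult, ivw, mr_egger, q_statistic
from .harmonize import HarmonizedSet

DEFAULT_N_SIM = 1000
DEFAULT_SIG = 0.05
HETEROGENEITY_ALPHA = 0.05


@dataclass
class PressoReport:
    """MR-PRESSO global, outlier and distortion test results."""

    rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outliers: set[str]
    corrected_result: MrResult | None
    distortion_pval: float | None
    n_sim: int
    seed: int


@dataclass
class SensitivityReport:
    """Full sensitivity block for one exposure-outcome cell."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept_block: EggerExtra | None
    presso: PressoReport | None
    loo: list[tuple[str, MrResult]] = field(default_factory=list)

    @property
    def heterogeneous(self) -> bool:
        return self.q_pval < HETEROGENEITY_ALPHA


def cochran_q(hset: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q, its degrees of freedom J - 1, and the chi-square p-value."""
    j = len(hset.records)
    if j < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 SNPs, got {j}")
    q = q_statistic(hset)
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


def _subset(hset: HarmonizedSet, keep_idx) -> HarmonizedSet:
    return HarmonizedSet(
        exposure_label=hset.exposure_label,
        outcome_label=hset.outcome_label,
        records=[hset.records[i] for i in keep_idx],
    )


def _loo_ivw_betas(g: np.ndarray, G: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effects IVW point estimates, vectorized."""
    num = g * G / sy**2
    den = g**2 / sy**2
    tot_num, tot_den = np.sum(num), np.sum(den)
    return (tot_num - num) / (tot_den - den)


def _presso_rss(g: np.ndarray, G: np.ndarray, sy: np.ndarray) -> tuple[np.ndarray, float]:
    """Standardized leave-one-out residuals and their sum of squares."""
    beta_loo = _loo_ivw_betas(g, G, sy)
    r = (G - beta_loo * g) / sy
    return r**2, float(np.sum(r**2))


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    sig: float = DEFAULT_SIG,
    model: str = "multiplicative_random",
) -> PressoReport:
    """MR-PRESSO global, outlier and distortion tests (seeded, deterministic)."""
    j = len(hset.records)
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 SNPs, got {j}")

    g = np.array([r.gamma_hat for r in hset.records])
    sx = np.array([r.sigma_x for r in hset.records])
    G = np.array([r.Gamma_hat for r in hset.records])
    sy = np.array([r.sigma_y for r in hset.records])
    snp_ids = [r.snp_id for r in hset.records]

    r2_obs, rss_obs = _presso_rss(g, G, sy)
    beta_loo = _loo_ivw_betas(g, G, sy)

    rng = np.random.default_rng(seed)
    rss_sim = np.empty(n_sim)
    r2_sim = np.empty((n_sim, j))
    for s in range(n_sim):
        g_star = rng.normal(g, sx)
        G_star = rng.normal(beta_loo * g, sy)  # expectation under no pleiotropy
        r2_s, rss_s = _presso_rss(g_star, G_star, sy)
        r2_sim[s] = r2_s
        rss_sim[s] = rss_s

    global_pval = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)

    outlier_pvals: dict[str, float] = {}
    outliers: set[str] = set()
    for idx, snp in enumerate(snp_ids):
        p_raw = (1.0 + np.sum(r2_sim[:, idx] >= r2_obs[idx])) / (n_sim + 1.0)
        p_adj = min(1.0, p_raw * j)  # Bonferroni over the J per-SNP tests
        outlier_pvals[snp] = p_adj
        if p_adj < sig:
            outliers.add(snp)

    corrected_result: MrResult | None = None
    distortion_pval: float | None = None
    if outliers:
        keep = [i for i, s in enumerate(snp_ids) if s not in outliers]
        if not keep:
            raise DegenerateCorrectionError("every SNP flagged as a MR-PRESSO outlier")
        full = ivw(hset, model=model)
        corrected_result = ivw(_subset(hset, keep), model=model)

        # distortion: is the corrected-vs-full shift larger than shifts from
        # random same-size subsets?
        d_obs = corrected_result.beta - full.beta
        k = len(keep)
        d_sim = np.empty(n_sim)
        idx_all = np.arange(j)
        for s in range(n_sim):
            sub = rng.choice(idx_all, size=k, replace=False)
            w = g[sub] ** 2 / sy[sub] ** 2
            d_sim[s] = np.sum(w * (G[sub] / g[sub])) / np.sum(w) - full.beta
        distortion_pval = float((1.0 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1.0))

    return PressoReport(
        rss_obs=rss_obs,
        global_pval=float(global_pval),
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        corrected_result=corrected_result,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(hset: HarmonizedSet, model: str = "multiplicative_random") -> list[tuple[str, MrResult]]:
    """IVW recomputed with each SNP excluded in turn, in input order.

    Subsets of size 1 fall back to the fixed-effects model, whose single-SNP
    estimate is the Wald ratio itself.
    """
    j = len(hset.records)
    if j < 2:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 2 SNPs, got {j}")
    results = []
    for i, rec in enumerate(hset.records):
        sub = _subset(hset, [k for k in range(j) if k != i])
        sub_model = model if len(sub.records) >= 2 else "fixed"
        results.append((rec.snp_id, ivw(sub, model=sub_model)))
    return results


def run_sensitivity(
    hset: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    sig: float = DEFAULT_SIG,
    model: str = "multiplicative_random",
) -> SensitivityReport:
    """Assemble the full sensitivity block; components needing more SNPs than
    available are reported as absent rather than failing the cell."""
    q, df, q_p = cochran_q(hset)
    egger_block = None
    if len(hset.records) >= 3:
        egger_block = mr_egger(hset).extra["egger"]
    presso = None
    if len(hset.records) >= 4:
        presso = mr_presso(hset, n_sim=n_sim, seed=seed, sig=sig, model=model)
    return SensitivityReport(
        q_stat=q,
        q_df=df,
        q_pval=q_p,
        egger_intercept_block=egger_block,
        presso=presso,
        loo=leave_one_out(hset, model=model),
    )
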