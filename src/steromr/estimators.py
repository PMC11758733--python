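"""The three two-sample MR estimators: IVW, MR-Egger, weighted median.

All three combine per-SNP Wald ratios beta_j = Gamma_hat_j / gamma_hat_j.

* IVW is the inverse-variance-weighted mean of Wald ratios with weights
  w_j = gamma_hat_j^2 / sigma_yj^2 — algebraically the slope of a weighted
  least-squares fit of outcome on exposure effects through the origin.
  The default multiplicative random-effects model inflates the fixed-effects
  SE by max(1, sqrt(Q / (J - 1))), never shrinking below it.
* MR-Egger adds a free intercept to the same weighted regression; a non-zero
  intercept estimates the average directional pleiotropy. Coefficient SEs use
  a multiplicative overdispersion factor max(1, sqrt(RSS_w / (J - 2))) and
  t-based p-values with J - 2 degrees of freedom. The fit requires the
  positive-exposure-effect orientation (see ``harmonize.orient_positive``).
* The weighted median interpolates sorted Wald ratios against cumulative
  midpoint weight percentiles at 50%; it is consistent when valid instruments
  carry more than half the total weight. Its SE comes from a seeded
  parametric bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, PreconditionError
from .harmonize import HarmonizedRecord, HarmonizedSet

IVW_LABEL = "IVW"
EGGER_LABEL = "MR-Egger"
WEIGHTED_MEDIAN_LABEL = "weighted-median"

DEFAULT_CI_LEVEL = 0.95
DEFAULT_N_BOOT = 1000


@dataclass
class EggerExtra:
    """MR-Egger intercept block: the directional-pleiotropy test."""

    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass
class MrResult:
    """One estimator's causal estimate on the log-odds and OR scales."""

    method: str
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    n_snps: int
    extra: dict = field(default_factory=dict)


def _arrays(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    g = np.array([r.gamma_hat for r in hset.records])
    sx = np.array([r.sigma_x for r in hset.records])
    G = np.array([r.Gamma_hat for r in hset.records])
    sy = np.array([r.sigma_y for r in hset.records])
    return g, sx, G, sy


def _require_nonzero_gamma(hset: HarmonizedSet) -> None:
    zeros = [r.snp_id for r in hset.records if r.gamma_hat == 0]
    if zeros:
        raise PreconditionError(f"zero exposure effect for SNP(s) {zeros}: Wald ratio undefined")


def wald_ratio(rec: HarmonizedRecord, second_order: bool = False) -> tuple[float, float]:
    """Per-SNP causal estimate Gamma_hat/gamma_hat and its delta-method SE.

    The first-order SE sigma_y/|gamma_hat| ignores exposure sampling error;
    ``second_order=True`` adds the Gamma_hat^2 sigma_x^2 / gamma_hat^4 term.
    """
    if rec.gamma_hat == 0:
        raise PreconditionError(f"zero exposure effect for SNP {rec.snp_id}: Wald ratio undefined")
    beta = rec.Gamma_hat / rec.gamma_hat
    var = rec.sigma_y**2 / rec.gamma_hat**2
    if second_order:
        var += rec.Gamma_hat**2 * rec.sigma_x**2 / rec.gamma_hat**4
    return beta, math.sqrt(var)


def to_odds_ratio(beta: float, se: float, level: float = DEFAULT_CI_LEVEL) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate to (OR, CI low, CI high)."""
    if se <= 0:
        raise PreconditionError(f"se must be positive, got {se}")
    if not 0 < level < 1:
        raise PreconditionError(f"confidence level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def _finish(method: str, beta: float, se: float, pval: float, n: int, level: float, extra=None) -> MrResult:
    or_, lo, hi = to_odds_ratio(beta, se, level)
    return MrResult(
        method=method,
        beta=beta,
        se=se,
        pval=pval,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        n_snps=n,
        extra=extra or {},
    )


def q_statistic(hset: HarmonizedSet) -> float:
    """Cochran's Q around the fixed-effects IVW estimate (the raw statistic)."""
    g, _, G, sy = _arrays(hset)
    w = g**2 / sy**2
    ratios = G / g
    beta_ivw = np.sum(w * ratios) / np.sum(w)
    return float(np.sum(w * (ratios - beta_ivw) ** 2))


def ivw(
    hset: HarmonizedSet,
    model: str = "multiplicative_random",
    level: float = DEFAULT_CI_LEVEL,
) -> MrResult:
    """Inverse-variance-weighted estimate across all instruments."""
    if model not in ("fixed", "multiplicative_random"):
        raise PreconditionError(f"unknown IVW model {model!r}")
    j = len(hset.records)
    minimum = 1 if model == "fixed" else 2
    if j < minimum:
        raise InsufficientInstrumentsError(f"IVW ({model}) needs >= {minimum} SNPs, got {j}")
    _require_nonzero_gamma(hset)

    g, _, G, sy = _arrays(hset)
    w = g**2 / sy**2
    beta = float(np.sum(g * G / sy**2) / np.sum(g**2 / sy**2))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    extra: dict = {"model": model}
    if model == "fixed":
        se = se_fixed
    else:
        q = q_statistic(hset)
        scale = max(1.0, math.sqrt(q / (j - 1)))
        se = se_fixed * scale
        extra["overdispersion_scale"] = scale
    pval = float(2.0 * stats.norm.sf(abs(beta / se)))
    return _finish(IVW_LABEL, beta, se, pval, j, level, extra)


def mr_egger(hset: HarmonizedSet, level: float = DEFAULT_CI_LEVEL) -> MrResult:
    """Weighted regression with a free pleiotropy intercept.

    The caller must first pass the set through ``orient_positive``; the slope
    is the causal estimate and the intercept the average pleiotropic effect.
    """
    j = len(hset.records)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {j}")
    g, _, G, sy = _arrays(hset)
    w = 1.0 / sy**2

    # weighted normal equations for y = b0 + b1 x
    X = np.column_stack([np.ones(j), g])
    XtW = X.T * w
    cov_unit = np.linalg.inv(XtW @ X)
    coef = cov_unit @ (XtW @ G)
    b0, b1 = float(coef[0]), float(coef[1])

    resid = G - X @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / (j - 2))  # multiplicative overdispersion, floored at 1
    se0, se1 = np.sqrt(phi * np.diag(cov_unit))

    df = j - 2
    p_slope = float(2.0 * stats.t.sf(abs(b1 / se1), df))
    p_intercept = float(2.0 * stats.t.sf(abs(b0 / se0), df))
    extra = {
        "egger": EggerExtra(intercept=b0, intercept_se=float(se0), intercept_pval=p_intercept),
        "rss_weighted": rss_w,
    }
    return _finish(EGGER_LABEL, b1, float(se1), p_slope, j, level, extra)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50th percentile of ratios under normalized weights."""
    order = np.argsort(ratios, kind="stable")
    b = ratios[order]
    wn = weights[order] / np.sum(weights)
    p = np.cumsum(wn) - wn / 2.0  # cumulative midpoint percentiles
    return float(np.interp(0.5, p, b))


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    level: float = DEFAULT_CI_LEVEL,
) -> MrResult:
    """Weighted-median causal estimate with parametric-bootstrap SE."""
    j = len(hset.records)
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {j}")
    if n_boot < 2:
        raise PreconditionError(f"n_boot must be >= 2, got {n_boot}")
    _require_nonzero_gamma(hset)

    g, sx, G, sy = _arrays(hset)
    ratios = G / g
    weights = g**2 / sy**2
    beta = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        g_star = rng.normal(g, sx)
        G_star = rng.normal(G, sy)
        ok = g_star != 0
        boot[i] = _weighted_median_point(G_star[ok] / g_star[ok], g_star[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boot, ddof=1))
    if se == 0:  # degenerate bootstrap (e.g. zero-noise fixtures)
        se = float(np.finfo(float).tiny)
        pval = 0.0 if beta != 0 else 1.0
    else:
        pval = float(2.0 * stats.norm.sf(abs(beta / se)))
    extra = {"n_boot": n_boot, "seed": seed}
    return _finish(WEIGHTED_MEDIAN_LABEL, beta, se, pval, j, level, extra)
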