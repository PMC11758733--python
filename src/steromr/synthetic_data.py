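"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generative model mirrors the instrumental-variable assumptions of
two-sample MR on a continuous standardized exposure and a log-odds outcome
scale. For SNP j with effect-allele frequency f_j and true exposure effect
gamma_j:

    sigma_xj   = 1 / sqrt(2 f_j (1 - f_j) n_exposure)
    gamma_hat_j = gamma_j + N(0, sigma_xj^2)
    Gamma_j    = theta * gamma_j + alpha_j (+ outlier shift)
    sigma_yj   = 1 / sqrt(2 f_j (1 - f_j) n_outcome)
    Gamma_hat_j = Gamma_j + N(0, sigma_yj^2)

alpha_j is the horizontal-pleiotropy term: zero (``none``), zero-mean
(``balanced``) or shifted (``directional``). The exclusion restriction holds
exactly iff the pleiotropy mode is ``none`` and no outlier shift is injected.

One global seed drives a counter-based substream per SNP, so extending a
panel never perturbs earlier draws. Default sample sizes (50,000 exposure /
100,000 outcome) and allele frequencies (uniform on 0.1-0.9) resemble the
hormone and stroke meta-analyses this kind of pipeline is pointed at. The
default effect-size scale gamma ~ N(0.15, 0.05^2) matches instruments that
small hormone GWAMAs can detect (|beta| around 0.1-0.3 per allele on a
standardized trait) and keeps the exposure-effect spread large relative to
its sampling noise (I^2_GX ~ 0.99), which the Egger regression needs for its
intercept to estimate average pleiotropy without regression dilution.

Winner's curse, case-control ascertainment and individual-level genotypes are
deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import ConfigError
from .sumstats_io import LdMatrix, SummaryStatRecord, SummaryStatsTable

#: non-palindromic allele pairs cycled over the panel by default
NON_PALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))

_MIN_P = 5e-324  # smallest subnormal double: keeps p-values in (0, 1]


@dataclass
class SimulationConfig:
    """Generating parameters for one two-sample summary-statistics panel."""

    j_snps: int = 30
    n_exposure: int = 50_000
    n_outcome: int = 100_000
    theta: float = 0.2
    gamma_dist: tuple[float, float] = (0.15, 0.05)
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    outlier_indices: frozenset[int] = field(default_factory=frozenset)
    outlier_shift: float = 0.0
    eaf_range: tuple[float, float] = (0.1, 0.9)
    ld_blocks: tuple[int, float] | None = None  # (block_size, within_r2)
    seed: int = 0
    zero_noise: bool = False  # infinite-sample limit: estimates are noise-free
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"

    def __post_init__(self) -> None:
        if self.j_snps < 1:
            raise ConfigError(f"j_snps must be >= 1, got {self.j_snps}")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ConfigError("sample sizes must be >= 2")
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise ConfigError(f"eaf_range must be strictly inside (0, 1), got {self.eaf_range}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "none" and self.pleiotropy_sd != 0:
            raise ConfigError("pleiotropy_mode 'none' requires pleiotropy_sd = 0")
        if self.pleiotropy_sd < 0:
            raise ConfigError("pleiotropy_sd must be >= 0")
        if any(i < 0 or i >= self.j_snps for i in self.outlier_indices):
            raise ConfigError("outlier_indices out of range")
        if self.ld_blocks is not None:
            size, r2 = self.ld_blocks
            if size < 1 or not 0 <= r2 <= 1:
                raise ConfigError(f"invalid ld_blocks {self.ld_blocks}")


@dataclass
class SimulationTruth:
    """Generating parameters paired with the simulated tables for recovery tests."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    outlier_indices: frozenset[int]


def _snp_rng(seed: int, j: int) -> np.random.Generator:
    # counter-based substream: one child generator per SNP index
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(j,)))


def _two_sided_p(beta: float, se: float) -> float:
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return min(1.0, max(_MIN_P, float(p)))


def _record(snp_id, chrom, pos, alleles, eaf, beta, se, n) -> SummaryStatRecord:
    return SummaryStatRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=alleles[0],
        other_allele=alleles[1],
        eaf=float(eaf),
        beta=float(beta),
        se=float(se),
        pval=_two_sided_p(beta, se),
        n=n,
    )


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, SimulationTruth]:
    """Generate exposure and outcome tables plus the generating truth."""
    j_snps = config.j_snps
    gamma = np.empty(j_snps)
    alpha = np.empty(j_snps)
    exp_records: list[SummaryStatRecord] = []
    out_records: list[SummaryStatRecord] = []

    mu_g, sd_g = config.gamma_dist
    lo, hi = config.eaf_range
    for j in range(j_snps):
        rng = _snp_rng(config.seed, j)
        eaf = rng.uniform(lo, hi)
        gamma[j] = rng.normal(mu_g, sd_g)

        het = 2.0 * eaf * (1.0 - eaf)
        sigma_x = 1.0 / np.sqrt(het * config.n_exposure)
        sigma_y = 1.0 / np.sqrt(het * config.n_outcome)

        if config.pleiotropy_mode == "none":
            alpha[j] = 0.0
        elif config.pleiotropy_mode == "balanced":
            alpha[j] = rng.normal(0.0, config.pleiotropy_sd)
        else:  # directional
            alpha[j] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd)

        shift = config.outlier_shift if j in config.outlier_indices else 0.0
        Gamma = config.theta * gamma[j] + alpha[j] + shift

        if config.zero_noise:
            gamma_hat, Gamma_hat = gamma[j], Gamma
        else:
            gamma_hat = gamma[j] + rng.normal(0.0, sigma_x)
            Gamma_hat = Gamma + rng.normal(0.0, sigma_y)

        alleles = NON_PALINDROMIC_PAIRS[j % len(NON_PALINDROMIC_PAIRS)]
        chrom = str((j % 22) + 1)
        pos = 1_000_000 + 20_000_000 * (j // 22)
        snp_id = f"rs{j + 1}"
        exp_records.append(
            _record(snp_id, chrom, pos, alleles, eaf, gamma_hat, sigma_x, config.n_exposure)
        )
        out_records.append(
            _record(snp_id, chrom, pos, alleles, eaf, Gamma_hat, sigma_y, config.n_outcome)
        )

    truth = SimulationTruth(
        theta=config.theta,
        gamma=gamma,
        alpha=alpha,
        outlier_indices=config.outlier_indices,
    )
    return (
        SummaryStatsTable(trait_label=config.exposure_label, records=exp_records),
        SummaryStatsTable(trait_label=config.outcome_label, records=out_records),
        truth,
    )


def simulate_ld_candidates(config: SimulationConfig) -> tuple[SummaryStatsTable, LdMatrix]:
    """Exposure candidates arranged in LD blocks for exercising clumping.

    SNPs sit at consecutive positions on one chromosome, inside a single
    clumping window. Within a block every pair shares r^2 = ``within_r2``;
    between blocks r^2 = 0. P-values increase along the panel so each block's
    first SNP is its most significant member (the expected index SNP).
    """
    if config.ld_blocks is None:
        raise ConfigError("simulate_ld_candidates requires ld_blocks to be set")
    block_size, within_r2 = config.ld_blocks
    j_snps = config.j_snps

    records: list[SummaryStatRecord] = []
    se = 0.01
    for j in range(j_snps):
        rng = _snp_rng(config.seed, j)
        eaf = rng.uniform(*config.eaf_range)
        pval = (j + 1) * 1e-8  # ascending: block leaders are most significant
        z = stats.norm.isf(pval / 2.0)
        alleles = NON_PALINDROMIC_PAIRS[j % len(NON_PALINDROMIC_PAIRS)]
        records.append(
            _record(f"rs{j + 1}", "1", 10_000 + 1_000 * j, alleles, eaf, z * se, se, config.n_exposure)
        )

    r2 = np.eye(j_snps)
    for a in range(j_snps):
        for b in range(j_snps):
            if a != b and a // block_size == b // block_size:
                r2[a, b] = within_r2
    ld = LdMatrix(
        snp_ids=[r.snp_id for r in records],
        r2=r2,
        positions={r.snp_id: (r.chrom, r.pos) for r in records},
    )
    return SummaryStatsTable(trait_label=config.exposure_label, records=records), ld


def make_palindromic_fixture(
    fraction: float, config: SimulationConfig
) -> tuple[SummaryStatsTable, SummaryStatsTable]:
    """Exposure/outcome pair where a fixed fraction of SNPs is palindromic."""
    if not 0 <= fraction <= 1:
        raise ConfigError(f"fraction must be in [0, 1], got {fraction}")
    exposure, outcome, _ = simulate_two_sample(config)
    k = int(round(fraction * config.j_snps))
    # deterministic choice of which SNPs become palindromic: evenly spread
    rng = _snp_rng(config.seed, config.j_snps)  # substream past the panel
    chosen = rng.choice(config.j_snps, size=k, replace=False) if k else np.array([], dtype=int)

    def _assign(table: SummaryStatsTable) -> SummaryStatsTable:
        new = list(table.records)
        for i in chosen:
            pair = PALINDROMIC_PAIRS[int(i) % len(PALINDROMIC_PAIRS)]
            new[i] = replace(new[i], effect_allele=pair[0], other_allele=pair[1])
        return SummaryStatsTable(trait_label=table.trait_label, records=new)

    return _assign(exposure), _assign(outcome)
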