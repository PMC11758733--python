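"""Shared builders for summary-statistic and harmonized fixtures."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from steromr import HarmonizedRecord, HarmonizedSet, SummaryStatRecord, SummaryStatsTable

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

ALLELE_CYCLE = (("A", "G"), ("T", "C"), ("A", "C"), ("T", "G"))


def make_record(
    snp_id: str,
    beta: float = 0.1,
    se: float = 0.01,
    pval: float = 1e-6,
    eaf: float | None = 0.3,
    n: int | None = 10_000,
    chrom: str = "1",
    pos: int = 1000,
    alleles: tuple[str, str] = ("A", "G"),
) -> SummaryStatRecord:
    return SummaryStatRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=alleles[0],
        other_allele=alleles[1],
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def make_table(records, label: str = "trait") -> SummaryStatsTable:
    return SummaryStatsTable(trait_label=label, records=list(records))


def make_hset(gammas, Gammas, sigma_x=0.01, sigma_y=0.01, label=("exp", "out")) -> HarmonizedSet:
    """Harmonized set from parallel effect arrays; scalar SEs are broadcast."""
    gammas = np.asarray(gammas, dtype=float)
    Gammas = np.asarray(Gammas, dtype=float)
    sx = np.broadcast_to(np.asarray(sigma_x, dtype=float), gammas.shape)
    sy = np.broadcast_to(np.asarray(sigma_y, dtype=float), gammas.shape)
    records = [
        HarmonizedRecord(
            snp_id=f"rs{i + 1}",
            gamma_hat=float(g),
            sigma_x=float(sxi),
            Gamma_hat=float(G),
            sigma_y=float(syi),
            effect_allele="A",
            other_allele="G",
            action="unchanged",
        )
        for i, (g, G, sxi, syi) in enumerate(zip(gammas, Gammas, sx, sy))
    ]
    return HarmonizedSet(exposure_label=label[0], outcome_label=label[1], records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


def random_hset(rng, j: int) -> HarmonizedSet:
    """A generic random instance for oracle cross-checks."""
    g = rng.normal(0.1, 0.05, j)
    g[g == 0] = 0.05
    sx = rng.uniform(0.005, 0.02, j)
    sy = rng.uniform(0.005, 0.03, j)
    G = 0.25 * g + rng.normal(0, 0.01, j)
    return make_hset(g, G, sx, sy)
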