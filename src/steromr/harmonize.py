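"""Allele harmonization of exposure and outcome summary statistics.

The exposure effect allele is the reference orientation throughout: the
outcome record is modified, never the exposure. Outcome alleles that are the
strand complement (A<->T, C<->G) of the exposure alleles are complemented
before re-matching, and swapped alleles flip the sign of the outcome beta
(and reflect its frequency). Palindromic SNPs (A/T or C/G) are ambiguous to
strand inference from labels alone and are dropped under the default policy;
an optional frequency-based policy keeps them when both frequencies are
informative (outside 0.42-0.58) and agree in direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .errors import PreconditionError
from .sumstats_io import SummaryStatRecord, SummaryStatsTable

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonize_pair action labels
UNCHANGED = "unchanged"
FLIPPED = "flipped"
STRAND_CORRECTED = "strand_corrected"
STRAND_CORRECTED_FLIPPED = "strand_corrected_flipped"

#: eaf band within which palindromic frequency inference is considered unsafe
AMBIGUOUS_EAF_BAND = (0.42, 0.58)


@dataclass(frozen=True)
class HarmonizedRecord:
    """Per-SNP aligned exposure/outcome effects on a common effect allele."""

    snp_id: str
    gamma_hat: float  # exposure beta
    sigma_x: float  # exposure SE
    Gamma_hat: float  # outcome beta aligned to the exposure effect allele
    sigma_y: float  # outcome SE
    effect_allele: str
    other_allele: str
    action: str

    def __post_init__(self) -> None:
        if not self.sigma_x > 0 or not self.sigma_y > 0:
            raise PreconditionError(f"{self.snp_id}: standard errors must be positive")


@dataclass
class Drop:
    """A SNP excluded during harmonization, with the reason."""

    snp_id: str
    reason: str


@dataclass
class HarmonizedSet:
    """Harmonized instruments for one exposure-outcome pair plus the drop log."""

    exposure_label: str
    outcome_label: str
    records: list[HarmonizedRecord] = field(default_factory=list)
    dropped: list[Drop] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def is_palindromic(rec: SummaryStatRecord) -> bool:
    return COMPLEMENT[rec.effect_allele] == rec.other_allele


def harmonize_pair(
    exp: SummaryStatRecord,
    out: SummaryStatRecord,
    policy: str = "drop",
) -> HarmonizedRecord | Drop:
    """Align one outcome record to the exposure effect allele.

    ``policy`` governs palindromic SNPs: ``"drop"`` (default) removes them;
    ``"infer"`` keeps those whose exposure and outcome frequencies are both
    outside the ambiguous band and on the same side of 0.5.
    """
    if exp.snp_id != out.snp_id:
        raise PreconditionError(f"snp_id mismatch: {exp.snp_id!r} vs {out.snp_id!r}")

    if is_palindromic(exp) or is_palindromic(out):
        if policy == "infer":
            lo, hi = AMBIGUOUS_EAF_BAND
            if (
                exp.eaf is not None
                and out.eaf is not None
                and not lo <= exp.eaf <= hi
                and not lo <= out.eaf <= hi
                and (exp.eaf < 0.5) == (out.eaf < 0.5)
            ):
                # same-side frequencies: same strand and orientation assumed
                return HarmonizedRecord(
                    snp_id=exp.snp_id,
                    gamma_hat=exp.beta,
                    sigma_x=exp.se,
                    Gamma_hat=out.beta,
                    sigma_y=out.se,
                    effect_allele=exp.effect_allele,
                    other_allele=exp.other_allele,
                    action=UNCHANGED,
                )
        return Drop(exp.snp_id, "palindromic")

    e = (exp.effect_allele, exp.other_allele)
    o = (out.effect_allele, out.other_allele)
    o_comp = (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele])

    if o == e:
        action, out_beta = UNCHANGED, out.beta
    elif o == (e[1], e[0]):
        action, out_beta = FLIPPED, -out.beta
    elif o_comp == e:
        action, out_beta = STRAND_CORRECTED, out.beta
    elif o_comp == (e[1], e[0]):
        action, out_beta = STRAND_CORRECTED_FLIPPED, -out.beta
    else:
        return Drop(exp.snp_id, "mismatch")

    return HarmonizedRecord(
        snp_id=exp.snp_id,
        gamma_hat=exp.beta,
        sigma_x=exp.se,
        Gamma_hat=out_beta,
        sigma_y=out.se,
        effect_allele=exp.effect_allele,
        other_allele=exp.other_allele,
        action=action,
    )


def harmonize_tables(
    exp: SummaryStatsTable,
    out: SummaryStatsTable,
    policy: str = "drop",
    outcome_label: str | None = None,
) -> HarmonizedSet:
    """Harmonize every exposure SNP against the outcome table.

    SNPs absent from the outcome are dropped as ``missing_in_outcome``;
    ordering follows the exposure input order.
    """
    out_by_id = out.by_id()
    hset = HarmonizedSet(
        exposure_label=exp.trait_label,
        outcome_label=outcome_label or out.trait_label,
    )
    for exp_rec in exp.records:
        out_rec = out_by_id.get(exp_rec.snp_id)
        if out_rec is None:
            hset.dropped.append(Drop(exp_rec.snp_id, "missing_in_outcome"))
            continue
        result = harmonize_pair(exp_rec, out_rec, policy=policy)
        if isinstance(result, Drop):
            hset.dropped.append(result)
        else:
            hset.records.append(result)
    if not hset.records:
        logger.warning(
            "harmonization of %s vs %s produced no usable SNPs",
            exp.trait_label,
            hset.outcome_label,
        )
    return hset


def orient_positive(hset: HarmonizedSet) -> HarmonizedSet:
    """Relabel alleles so every exposure effect is non-negative.

    Negating both betas leaves every Wald ratio unchanged; this fixes the
    orientation convention required by the Egger regression, which is not
    invariant to per-SNP sign flips. Idempotent.
    """
    oriented = []
    for rec in hset.records:
        if rec.gamma_hat < 0:
            rec = replace(
                rec,
                gamma_hat=-rec.gamma_hat,
                Gamma_hat=-rec.Gamma_hat,
                effect_allele=rec.other_allele,
                other_allele=rec.effect_allele,
            )
        oriented.append(rec)
    return HarmonizedSet(
        exposure_label=hset.exposure_label,
        outcome_label=hset.outcome_label,
        records=oriented,
        dropped=list(hset.dropped),
    )
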