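"""Instrument selection: significance filter, LD clumping, exclusions, F-statistics.

Instrument strength is summarized by the F-statistic

    F = (N - K - 1) * R^2 / (K * (1 - R^2))

with N the exposure sample size, K the number of instruments and R^2 the
fraction of exposure variance they explain. Per-SNP R^2 uses the
standardized-effect approximation

    R^2_j = 2 f_j (1 - f_j) beta_j^2 / (2 f_j (1 - f_j) beta_j^2 + 2 f_j (1 - f_j) se_j^2 n_j)

which reduces to 2 f (1 - f) beta^2 when the trait has unit variance; the
n-normalized denominator guards unstandardized inputs. Users with a better
variance-explained estimate can supply their own per-SNP R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import PreconditionError
from .sumstats_io import LdMatrix, SummaryStatRecord, SummaryStatsTable

logger = logging.getLogger(__name__)

#: conventional weak-instrument cutoff
DEFAULT_F_MIN = 10.0
#: locus-wide significance used when genome-wide (5e-8) yields too few SNPs
DEFAULT_PVAL_THRESHOLD = 1e-5
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_KB = 10_000.0


@dataclass
class InstrumentSet:
    """Selected instruments with their variance-explained and strength summary."""

    exposure_label: str
    records: list[SummaryStatRecord]
    per_snp_r2: dict[str, float]
    aggregate_r2: float
    f_statistic: float
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)


def filter_by_pvalue(table: SummaryStatsTable, threshold: float) -> SummaryStatsTable:
    """Keep records with p strictly below ``threshold``, preserving input order."""
    if not 0 < threshold <= 1:
        raise PreconditionError(f"p-value threshold must be in (0, 1], got {threshold}")
    kept = [r for r in table.records if r.pval < threshold]
    logger.info("p < %g filter: %d of %d SNPs retained", threshold, len(kept), len(table))
    if not kept:
        logger.warning("p-value filter left no SNPs for %s", table.trait_label)
    return SummaryStatsTable(trait_label=table.trait_label, records=kept)


def _clump_sort_key(rec: SummaryStatRecord):
    # ties on p broken by (chrom, pos, snp_id) for reproducibility
    return (rec.pval, rec.chrom or "", rec.pos or 0, rec.snp_id)


def ld_clump(
    table: SummaryStatsTable,
    ld: LdMatrix,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_KB,
    selection_log: list[tuple[str, str, str]] | None = None,
) -> SummaryStatsTable:
    """Greedy p-value-ordered clumping to approximately independent index SNPs.

    Repeatedly takes the remaining SNP with the smallest p-value as an index
    SNP and discards remaining SNPs on the same chromosome with
    ``|pos_a - pos_b| <= window_kb * 1000`` (closed interval) and pairwise
    r^2 > ``r2_max``. Output order follows selection (ascending p), so the
    result is independent of input record order.
    """
    for rec in table.records:
        rec.require("chrom", "pos") if (rec.chrom is None or rec.pos is None) else None
        if not ld.default_zero and rec.snp_id not in ld:
            raise PreconditionError(f"SNP {rec.snp_id!r} absent from square-format LD matrix")

    window_bp = window_kb * 1000.0
    remaining = sorted(table.records, key=_clump_sort_key)
    index_snps: list[SummaryStatRecord] = []
    while remaining:
        index = remaining.pop(0)
        index_snps.append(index)
        survivors = []
        for rec in remaining:
            same_chrom = rec.chrom == index.chrom
            in_window = same_chrom and abs(rec.pos - index.pos) <= window_bp
            if in_window and ld.get(index.snp_id, rec.snp_id) > r2_max:
                logger.debug("clump: %s discarded (r2 with index %s)", rec.snp_id, index.snp_id)
                if selection_log is not None:
                    selection_log.append((rec.snp_id, "clumped", f"r2>{r2_max} with {index.snp_id}"))
            else:
                survivors.append(rec)
        remaining = survivors
    logger.info("LD clumping: %d index SNPs from %d input SNPs", len(index_snps), len(table))
    return SummaryStatsTable(trait_label=table.trait_label, records=index_snps)


def exclude_snps(
    table: SummaryStatsTable,
    exclusion_list: set[str],
    reason_label: str = "excluded",
    selection_log: list[tuple[str, str, str]] | None = None,
) -> SummaryStatsTable:
    """Remove confounder-associated SNPs named in a user-supplied exclusion list."""
    kept = []
    for rec in table.records:
        if rec.snp_id in exclusion_list:
            logger.info("excluding %s (%s)", rec.snp_id, reason_label)
            if selection_log is not None:
                selection_log.append((rec.snp_id, "excluded", reason_label))
        else:
            kept.append(rec)
    return SummaryStatsTable(trait_label=table.trait_label, records=kept)


def per_snp_r2(record: SummaryStatRecord) -> float:
    """Fraction of exposure variance explained by one SNP, in [0, 1)."""
    record.require("eaf", "n")
    maf_var = 2.0 * record.eaf * (1.0 - record.eaf)
    num = maf_var * record.beta**2
    denom = num + maf_var * record.se**2 * record.n
    return num / denom if denom > 0 else 0.0


def f_statistic(n: int, k: int, r2: float) -> float:
    """Instrument-strength F for K instruments explaining R^2 in N samples."""
    if k < 1:
        raise PreconditionError(f"k must be >= 1, got {k}")
    if not 0 <= r2 < 1:
        raise PreconditionError(f"r2 must be in [0, 1), got {r2}")
    if n <= k + 1:
        raise PreconditionError(f"n must exceed k + 1 (n={n}, k={k})")
    return (n - k - 1) * r2 / (k * (1.0 - r2))


def build_instrument_set(table: SummaryStatsTable, selection_log=None) -> InstrumentSet:
    """Assemble an InstrumentSet, computing per-SNP R^2 and the aggregate F."""
    r2_map = {rec.snp_id: per_snp_r2(rec) for rec in table.records}
    agg = sum(r2_map.values())
    k = len(table.records)
    if k:
        n_min = min(rec.n for rec in table.records)
        f_agg = f_statistic(n_min, k, agg) if agg < 1 else float("inf")
    else:
        f_agg = 0.0
    return InstrumentSet(
        exposure_label=table.trait_label,
        records=list(table.records),
        per_snp_r2=r2_map,
        aggregate_r2=agg,
        f_statistic=f_agg,
        selection_log=list(selection_log or []),
    )


def filter_weak_instruments(iset: InstrumentSet, f_min: float = DEFAULT_F_MIN) -> InstrumentSet:
    """Drop SNPs whose single-instrument F = f_statistic(n, 1, R^2_j) is <= f_min."""
    kept: list[SummaryStatRecord] = []
    log = list(iset.selection_log)
    for rec in iset.records:
        f_j = f_statistic(rec.n, 1, iset.per_snp_r2[rec.snp_id])
        if f_j > f_min:
            kept.append(rec)
        else:
            logger.info("weak instrument %s removed (F=%.3g <= %g)", rec.snp_id, f_j, f_min)
            log.append((rec.snp_id, "weak_instrument", f"F={f_j:.4g}<= {f_min:g}"))
    table = SummaryStatsTable(trait_label=iset.exposure_label, records=kept)
    return build_instrument_set(table, selection_log=log)


def read_exclusion_list(path) -> set[str]:
    """Read a TSV exclusion list ``snp_id<TAB>reason?`` (header optional)."""
    ids: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if not parts[0].strip():
                continue
            if i == 0 and parts[0].strip().lower() in ("snp_id", "snp", "rsid"):
                continue
            ids.add(parts[0].strip())
    return ids
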