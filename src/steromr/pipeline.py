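"""End-to-end analysis of exposure x outcome grids and report writing.

Each cell runs the full workflow: p-value filter -> confounder exclusion ->
LD clumping (when an LD matrix is supplied) -> weak-instrument (F) filter ->
allele harmonization -> positive orientation -> IVW, MR-Egger and weighted
median -> Cochran's Q, MR-PRESSO and leave-one-out. Every dropped SNP is
auditable through the selection and harmonization logs.

Significance follows a Bonferroni correction whose denominator is the number
of EXPOSURES (not exposures x outcomes): with five exposures the corrected
threshold is 0.05 / 5 = 0.01, and p-values between that threshold and the
conventional 0.05 are labelled suggestive. This exposure-count denominator is
a deliberate, documented convention of the analysis this package reproduces.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import estimators, instruments, sensitivity
from .harmonize import HarmonizedSet, harmonize_tables, orient_positive
from .sumstats_io import LdMatrix, SummaryStatsTable

logger = logging.getLogger(__name__)

SIGNIFICANT = "significant"
SUGGESTIVE = "suggestive"
NONE = "none"

CONVENTIONAL_ALPHA = 0.05


@dataclass
class Settings:
    """All thresholds and seeds for one run; recorded verbatim in the manifest."""

    pval_threshold: float = instruments.DEFAULT_PVAL_THRESHOLD
    clump_r2: float = instruments.DEFAULT_CLUMP_R2
    clump_kb: float = instruments.DEFAULT_CLUMP_KB
    f_min: float = instruments.DEFAULT_F_MIN
    skip_f_filter: bool = False  # for inputs lacking eaf or n
    palindromic_policy: str = "drop"
    ivw_model: str = "multiplicative_random"
    n_boot: int = estimators.DEFAULT_N_BOOT
    n_sim: int = sensitivity.DEFAULT_N_SIM
    sig: float = sensitivity.DEFAULT_SIG
    ci_level: float = estimators.DEFAULT_CI_LEVEL
    seed: int = 0


@dataclass
class CellResult:
    """One exposure-outcome cell: estimates, sensitivity block, audit trail."""

    exposure_label: str
    outcome_label: str
    results: dict[str, estimators.MrResult] = field(default_factory=dict)
    sensitivity: sensitivity.SensitivityReport | None = None
    harmonized: HarmonizedSet | None = None
    failed: bool = False
    failure_reason: str | None = None
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)


@dataclass
class GridResult:
    """All cells of an exposures x outcomes grid plus significance labels."""

    cells: dict[tuple[str, str], CellResult]
    significance: dict[tuple[str, str], str]
    alpha_bonferroni: float
    n_exposures: int
    settings: Settings


def classify_significance(pval: float, n_exposures: int) -> str:
    """Label a p-value under the exposure-count Bonferroni scheme."""
    if n_exposures < 1:
        raise ValueError(f"n_exposures must be >= 1, got {n_exposures}")
    alpha = CONVENTIONAL_ALPHA / n_exposures
    if pval < alpha:
        return SIGNIFICANT
    if pval < CONVENTIONAL_ALPHA:
        return SUGGESTIVE
    return NONE


def run_mr_analysis(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    settings: Settings | None = None,
    ld: LdMatrix | None = None,
    exclusion_list: set[str] | None = None,
) -> CellResult:
    """Run the full single-cell workflow; failures are recorded, not raised."""
    settings = settings or Settings()
    cell = CellResult(exposure_label=exposure.trait_label, outcome_label=outcome.trait_label)
    log = cell.selection_log

    table = instruments.filter_by_pvalue(exposure, settings.pval_threshold)
    if exclusion_list:
        table = instruments.exclude_snps(table, exclusion_list, "confounder_associated", log)
    if ld is not None:
        table = instruments.ld_clump(table, ld, settings.clump_r2, settings.clump_kb, log)
    if not settings.skip_f_filter and len(table):
        iset = instruments.build_instrument_set(table, selection_log=log)
        iset = instruments.filter_weak_instruments(iset, settings.f_min)
        cell.selection_log = iset.selection_log
        table = SummaryStatsTable(trait_label=table.trait_label, records=iset.records)

    hset = orient_positive(
        harmonize_tables(table, outcome, policy=settings.palindromic_policy)
    )
    cell.harmonized = hset
    j = len(hset.records)
    if j == 0:
        cell.failed = True
        cell.failure_reason = "no_instruments"
        return cell

    cell.results["IVW"] = estimators.ivw(
        hset,
        model=settings.ivw_model if j >= 2 else "fixed",
        level=settings.ci_level,
    )
    if j >= 3:
        cell.results["MR-Egger"] = estimators.mr_egger(hset, level=settings.ci_level)
        cell.results["weighted-median"] = estimators.weighted_median(
            hset, n_boot=settings.n_boot, seed=settings.seed, level=settings.ci_level
        )
    else:
        cell.failed = True
        cell.failure_reason = f"only_{j}_instruments_after_harmonization"

    if j >= 2:
        cell.sensitivity = sensitivity.run_sensitivity(
            hset,
            n_sim=settings.n_sim,
            seed=settings.seed,
            sig=settings.sig,
            model=settings.ivw_model,
        )
    return cell


def run_grid(
    exposures: list[SummaryStatsTable],
    outcomes: list[SummaryStatsTable],
    settings: Settings | None = None,
    lds: dict[str, LdMatrix] | None = None,
    exclusion_lists: dict[str, set[str]] | None = None,
) -> GridResult:
    """Analyze every exposure-outcome pair independently.

    Per-cell failure never aborts the grid. The Bonferroni threshold derives
    from the exposure count; significance labels use the IVW p-value.
    """
    if not exposures or not outcomes:
        raise ValueError("run_grid needs at least one exposure and one outcome")
    settings = settings or Settings()
    n_exposures = len(exposures)
    cells: dict[tuple[str, str], CellResult] = {}
    labels: dict[tuple[str, str], str] = {}
    for exp in exposures:
        ld = (lds or {}).get(exp.trait_label)
        excl = (exclusion_lists or {}).get(exp.trait_label)
        for out in outcomes:
            key = (exp.trait_label, out.trait_label)
            try:
                cell = run_mr_analysis(exp, out, settings, ld=ld, exclusion_list=excl)
            except Exception as exc:  # a broken cell must not take down the grid
                logger.exception("cell %s failed", key)
                cell = CellResult(*key, failed=True, failure_reason=f"error: {exc}")
            cells[key] = cell
            ivw_res = cell.results.get("IVW")
            labels[key] = (
                classify_significance(ivw_res.pval, n_exposures) if ivw_res else NONE
            )
    return GridResult(
        cells=cells,
        significance=labels,
        alpha_bonferroni=CONVENTIONAL_ALPHA / n_exposures,
        n_exposures=n_exposures,
        settings=settings,
    )


def _slug(*parts: str) -> str:
    return "__".join(p.replace("/", "-").replace(" ", "_") for p in parts)


def _tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(repr(v) if isinstance(v, float) else str(v) for v in row) + "\n")


def write_reports(grid: GridResult, out_dir) -> None:
    """Emit the forest table, per-cell scatter and leave-one-out data,
    sensitivity summary, and a machine-readable run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    forest_rows, sens_rows = [], []
    for (exp_l, out_l), cell in grid.cells.items():
        label = grid.significance[(exp_l, out_l)]
        for method, res in cell.results.items():
            forest_rows.append(
                [exp_l, out_l, method, res.n_snps, res.beta, res.se,
                 res.or_, res.ci_low, res.ci_high, res.pval, label]
            )
        if cell.failed:
            forest_rows.append(
                [exp_l, out_l, "FAILED", 0, "NA", "NA", "NA", "NA", "NA",
                 "NA", cell.failure_reason or "unknown"]
            )

        if cell.harmonized is not None and cell.harmonized.records:
            scatter_rows = [
                [r.snp_id, r.gamma_hat, r.sigma_x, r.Gamma_hat, r.sigma_y, r.action]
                for r in cell.harmonized.records
            ]
            # fitted lines per method: slope (+ intercept for Egger)
            for method, res in cell.results.items():
                intercept = 0.0
                if method == "MR-Egger":
                    intercept = res.extra["egger"].intercept
                scatter_rows.append([f"fit:{method}", res.beta, "NA", intercept, "NA", "fitted_line"])
            _tsv(
                out / f"scatter__{_slug(exp_l, out_l)}.tsv",
                ["snp_id", "gamma_hat", "sigma_x", "Gamma_hat", "sigma_y", "action"],
                scatter_rows,
            )

        rep = cell.sensitivity
        if rep is not None:
            _tsv(
                out / f"leave_one_out__{_slug(exp_l, out_l)}.tsv",
                ["excluded_snp_id", "n_snps", "beta", "se", "or", "ci_low", "ci_high", "pval"],
                [
                    [snp, r.n_snps, r.beta, r.se, r.or_, r.ci_low, r.ci_high, r.pval]
                    for snp, r in rep.loo
                ],
            )
            egger = rep.egger_intercept_block
            presso = rep.presso
            sens_rows.append(
                [
                    exp_l, out_l, rep.q_stat, rep.q_df, rep.q_pval,
                    egger.intercept if egger else "NA",
                    egger.intercept_se if egger else "NA",
                    egger.intercept_pval if egger else "NA",
                    presso.global_pval if presso else "NA",
                    ";".join(sorted(presso.outliers)) if presso and presso.outliers else "",
                    presso.corrected_result.beta if presso and presso.corrected_result else "NA",
                    presso.distortion_pval if presso and presso.distortion_pval is not None else "NA",
                ]
            )

    _tsv(
        out / "forest.tsv",
        ["exposure", "outcome", "method", "n_snps", "beta", "se", "or",
         "ci_low", "ci_high", "pval", "significance"],
        forest_rows,
    )
    _tsv(
        out / "sensitivity.tsv",
        ["exposure", "outcome", "q_stat", "q_df", "q_pval", "egger_intercept",
         "egger_intercept_se", "egger_intercept_pval", "presso_global_pval",
         "presso_outliers", "presso_corrected_beta", "presso_distortion_pval"],
        sens_rows,
    )

    manifest = {
        "settings": asdict(grid.settings),
        "alpha_bonferroni": grid.alpha_bonferroni,
        "n_exposures": grid.n_exposures,
        "cells": [list(k) for k in grid.cells],
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def rerun_from_settings(settings: Settings, seed: int | None = None) -> Settings:
    """Copy settings, optionally overriding the run-level seed."""
    return replace(settings, seed=settings.seed if seed is None else seed)
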