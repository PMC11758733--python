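"""Reading, validating and writing GWAS summary statistics and LD matrices.

The canonical dialect is tab-separated with the fixed header
``snp_id chrom pos effect_allele other_allele eaf beta se pval n``.
Foreign dialects (``A1``/``A2``, ``freq``, ``b``, ``p`` ...) are handled by an
explicit ``column_map`` supplied by the caller rather than guessed, so parsing
is deterministic. Positions are 1-based base pairs, the usual convention for
GWAS summary statistics. Only biallelic single-base SNPs are accepted; indels
and multiallelic records are rejected at read time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DuplicateSnpError, FormatError, PreconditionError

VALID_ALLELES = frozenset("ACGT")

CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: columns that must be present (directly or via column_map) in any input
REQUIRED_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``eaf`` (effect-allele frequency) and ``n`` (sample size) may be absent
    (``None``); operations that need them raise :class:`PreconditionError`
    naming the missing field.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise FormatError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise FormatError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not 0 < self.pval <= 1:
            raise FormatError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise FormatError(f"{self.snp_id}: eaf must be in (0, 1), got {self.eaf}")
        if self.n is not None and self.n <= 0:
            raise FormatError(f"{self.snp_id}: n must be positive, got {self.n}")

    def require(self, *fields_: str) -> None:
        """Raise PreconditionError if any named optional field is absent."""
        for name in fields_:
            if getattr(self, name) is None:
                raise PreconditionError(f"{self.snp_id}: required field {name!r} is missing")


@dataclass
class SummaryStatsTable:
    """Ordered collection of per-SNP records for one trait, unique by snp_id."""

    trait_label: str
    records: list[SummaryStatRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.snp_id in seen:
                raise DuplicateSnpError(f"duplicate snp_id {rec.snp_id!r} in {self.trait_label!r}")
            seen.add(rec.snp_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def by_id(self) -> dict[str, SummaryStatRecord]:
        return {r.snp_id: r for r in self.records}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {col: getattr(rec, col) for col in CANONICAL_COLUMNS}
            for rec in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass
class LdMatrix:
    """Pairwise squared-correlation (r^2) matrix over an ordered SNP panel."""

    snp_ids: list[str]
    r2: np.ndarray
    positions: dict[str, tuple[str, int]] | None = None
    #: long-format inputs default absent pairs to r^2 = 0; square inputs do not
    default_zero: bool = False

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise FormatError(f"r2 matrix shape {self.r2.shape} does not match {k} SNP ids")
        if np.any((self.r2 < 0) | (self.r2 > 1)):
            raise FormatError("r2 values must lie in [0, 1]")
        if not np.allclose(self.r2, self.r2.T, atol=1e-9, rtol=0):
            raise FormatError("r2 matrix is asymmetric beyond 1e-9 tolerance")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-9):
            raise FormatError("r2 matrix diagonal must be 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, a: str, b: str) -> float:
        """Pairwise r^2; absent pairs are 0 only for long-format matrices."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            if self.default_zero:
                return 0.0
            missing = a if ia is None else b
            raise PreconditionError(f"SNP {missing!r} absent from square-format LD matrix")
        return float(self.r2[ia, ib])


def _check_pval_consistency(rec: SummaryStatRecord) -> None:
    # two-sided normal p implied by beta/se; 10% relative tolerance, warning only
    z = abs(rec.beta / rec.se)
    implied = 2.0 * stats.norm.sf(z)
    if implied <= 0:  # underflow region: printed p-values are unreliable there anyway
        return
    if not math.isclose(rec.pval, implied, rel_tol=0.10):
        warnings.warn(
            f"{rec.snp_id}: reported p={rec.pval:.3g} differs from |beta/se|-implied "
            f"p={implied:.3g} by more than 10%",
            stacklevel=3,
        )


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_label: str | None = None,
    validate_pvals: bool = True,
) -> SummaryStatsTable:
    """Read a TSV of summary statistics into a :class:`SummaryStatsTable`.

    ``column_map`` maps dialect column names to canonical names, e.g.
    ``{"A1": "effect_allele", "b": "beta"}``. Rows failing type coercion are
    rejected with their (1-based data) row numbers reported in a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records: list[SummaryStatRecord] = []
    bad_rows: list[int] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            snp_id = str(row_d["snp_id"]).strip()
            rec = SummaryStatRecord(
                snp_id=snp_id,
                effect_allele=str(row_d["effect_allele"]).strip().upper(),
                other_allele=str(row_d["other_allele"]).strip().upper(),
                beta=float(row_d["beta"]),
                se=float(row_d["se"]),
                pval=float(row_d["pval"]),
                chrom=_opt_str(row_d.get("chrom")),
                pos=_opt_int(row_d.get("pos")),
                eaf=_opt_float(row_d.get("eaf")),
                n=_opt_int(row_d.get("n")),
            )
        except (FormatError, ValueError, TypeError):
            # covers type-coercion failures, indel/multiallelic alleles and
            # out-of-range se/eaf/pval alike: the row is rejected, not the file
            bad_rows.append(i)
            continue
        if rec.snp_id in seen:
            raise DuplicateSnpError(f"{path}: duplicate snp_id {rec.snp_id!r}")
        seen.add(rec.snp_id)
        if validate_pvals:
            _check_pval_consistency(rec)
        records.append(rec)

    if bad_rows:
        warnings.warn(f"{path}: rejected {len(bad_rows)} malformed row(s): {bad_rows}", stacklevel=2)
    label = trait_label if trait_label is not None else str(path)
    return SummaryStatsTable(trait_label=label, records=records)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() in ("", "NA", "nan"):
        return None
    return str(v).strip()


def _opt_float(v) -> float | None:
    s = _opt_str(v)
    return None if s is None else float(s)


def _opt_int(v) -> int | None:
    s = _opt_str(v)
    return None if s is None else int(float(s))


def write_sumstats(table: SummaryStatsTable, path) -> None:
    """Write a table in the canonical TSV dialect with round-trippable floats."""
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for rec in table.records:
            fields_ = []
            for col in CANONICAL_COLUMNS:
                v = getattr(rec, col)
                if v is None:
                    fields_.append("NA")
                elif isinstance(v, float):
                    fields_.append(repr(v))  # shortest round-trip representation
                else:
                    fields_.append(str(v))
            fh.write("\t".join(fields_) + "\n")


def read_ld_matrix(path) -> LdMatrix:
    """Read an LD (r^2) matrix, auto-detecting square vs long format.

    Square format: header row of SNP ids (first cell is a corner label),
    one labelled row per SNP. Long format: three columns
    ``snp_a<TAB>snp_b<TAB>r2``; pairs not listed default to r^2 = 0.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty LD matrix file")
    header = lines[0].split("\t")
    data_rows = [ln.split("\t") for ln in lines[1:]]

    is_square = (
        len(header) >= 2
        and len(data_rows) == len(header) - 1
        and all(len(r) == len(header) for r in data_rows)
        and [r[0] for r in data_rows] == header[1:]
    )
    if is_square:
        snp_ids = header[1:]
        try:
            mat = np.array([[float(x) for x in r[1:]] for r in data_rows])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric entry in square LD matrix: {exc}") from exc
        return LdMatrix(snp_ids=snp_ids, r2=mat, default_zero=False)

    # long format: id pairs with r2; symmetrize, absent pairs default to 0
    ids: list[str] = []
    index: dict[str, int] = {}
    triples: list[tuple[str, str, float]] = []
    rows = data_rows if header[0].lower() in ("snp_a", "snp_id", "id1", "snp1") else [header] + data_rows
    for r in rows:
        if len(r) != 3:
            raise FormatError(f"{path}: long-format rows need 3 fields, got {len(r)}")
        a, b, v = r[0], r[1], float(r[2])
        if not 0 <= v <= 1:
            raise FormatError(f"{path}: r2 value {v} outside [0, 1] for pair ({a}, {b})")
        for s in (a, b):
            if s not in index:
                index[s] = len(ids)
                ids.append(s)
        triples.append((a, b, v))
    mat = np.eye(len(ids))
    for a, b, v in triples:
        ia, ib = index[a], index[b]
        if ia != ib:
            mat[ia, ib] = mat[ib, ia] = v
    return LdMatrix(snp_ids=ids, r2=mat, default_zero=True)


def write_ld_matrix(ld: LdMatrix, path) -> None:
    """Write an LD matrix in square TSV format."""
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(ld.snp_ids) + "\n")
        for i, s in enumerate(ld.snp_ids):
            fh.write(s + "\t" + "\t".join(repr(float(x)) for x in ld.r2[i]) + "\n")


def with_alleles(rec: SummaryStatRecord, effect_allele: str, other_allele: str) -> SummaryStatRecord:
    """Copy of a record with relabelled alleles (used by fixtures and tests)."""
    return replace(rec, effect_allele=effect_allele, other_allele=other_allele)
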