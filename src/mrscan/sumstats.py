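"""Reading, validating and writing GWAS summary statistics.

The on-disk dialect is tab-separated text with a header row.  The default
column names are ``variant_id, chrom, pos, ea, oa, eaf, beta, se, pval, n``;
a dialect mapping lets files with other headers (e.g. GWAS-SSF-style) be
ingested without rewriting them.  Missing values are written as ``.`` and
either ``.`` or the empty string is accepted on input.  Files ending in
``.gz`` are transparently (de)compressed.

In memory a trait's statistics live in a :class:`GwasSummary`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per variant.  Per-variant
effect sizes are interpreted as per-allele effects on the trait in SD units
(the usual scale for quantitative-trait GWAS).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("mrscan")

#: canonical column order of the sumstats dialect
COLUMNS = ["variant_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]

#: tokens treated as missing on input
_MISSING = {".", "", "na", "nan", "NA", "NaN"}

#: smallest positive double; p = 0 inputs are clamped here so -log10(p) stays finite
TINY_P = float(np.nextafter(0.0, 1.0))

_VALID_ALLELES = frozenset("ACGT")


class SumstatsError(ValueError):
    """Raised for unreadable files or unresolvable column dialects."""


@dataclass
class ValidationReport:
    """Counts of per-rule invariant violations found in one table.

    ``rows_rejected`` counts input rows dropped during parsing (non-numeric
    fields, invariant violations); ``duplicates_dropped`` counts rows removed
    because their variant_id repeated an earlier one.
    """

    counts: dict[str, int] = field(default_factory=dict)
    rows_rejected: int = 0
    duplicates_dropped: int = 0

    def add(self, rule: str, n: int = 1) -> None:
        if n:
            self.counts[rule] = self.counts.get(rule, 0) + n

    @property
    def n_violations(self) -> int:
        return sum(self.counts.values())

    def ok(self) -> bool:
        return self.n_violations == 0


@dataclass
class SummaryRecord:
    """A single variant's association statistics for one trait."""

    variant_id: str
    chrom: str
    pos: int
    ea: str
    oa: str
    eaf: float  # NaN when missing
    beta: float
    se: float
    pval: float
    n: float  # NaN when missing

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.ea, self.oa))


@dataclass
class GwasSummary:
    """Summary statistics of one trait (exposure or outcome role).

    ``table`` holds one row per variant in the canonical column order; variant
    ids are unique and input order is preserved.
    """

    trait_id: str
    trait_type: str  # "exposure" | "outcome"
    table: pd.DataFrame
    validation: ValidationReport = field(default_factory=ValidationReport)

    def __post_init__(self) -> None:
        if self.trait_type not in ("exposure", "outcome"):
            raise ValueError(f"trait_type must be exposure|outcome, got {self.trait_type!r}")
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"GwasSummary table lacks columns {missing}")

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.table["variant_id"])

    def records(self) -> Iterator[SummaryRecord]:
        for row in self.table.itertuples(index=False):
            yield SummaryRecord(
                variant_id=row.variant_id, chrom=row.chrom, pos=int(row.pos),
                ea=row.ea, oa=row.oa, eaf=float(row.eaf), beta=float(row.beta),
                se=float(row.se), pval=float(row.pval), n=float(row.n),
            )

    def get(self, variant_id: str) -> SummaryRecord:
        sub = self.table[self.table["variant_id"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        return next(GwasSummary(self.trait_id, self.trait_type, sub).records())

    def subset(self, variant_ids) -> "GwasSummary":
        keep = self.table[self.table["variant_id"].isin(set(variant_ids))]
        return GwasSummary(self.trait_id, self.trait_type, keep.reset_index(drop=True))


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_float(token: str) -> float:
    token = token.strip()
    if token in _MISSING:
        return np.nan
    return float(token)


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "exposure",
) -> GwasSummary:
    """Read one trait's summary statistics from a tab-separated file.

    Parameters
    ----------
    path:
        File to read; ``.gz`` suffix triggers decompression.
    dialect:
        Mapping from canonical column names to the names used in the file's
        header, for files not written in the default dialect.  Only mappings
        that differ from the default need to be given.
    trait_id:
        Identifier of the trait; defaults to the file's base name.
    trait_type:
        Role of the trait, ``"exposure"`` or ``"outcome"``.

    Rows with non-numeric or invariant-violating fields are rejected (not an
    error); each rejection is logged and counted in the returned summary's
    ``validation`` report.  A duplicated variant_id keeps the first row.
    """
    dialect = dict(dialect or {})
    colmap = {canon: dialect.get(canon, canon) for canon in COLUMNS}

    report = ValidationReport()
    rows: list[tuple] = []
    seen: set[str] = set()

    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise SumstatsError(f"{path}: empty file, expected a header row")
        header = header_line.rstrip("\n").split("\t")
        index: dict[str, int] = {}
        for canon in COLUMNS:
            name = colmap[canon]
            if name not in header:
                raise SumstatsError(f"{path}: mandatory column {name!r} (for {canon!r}) not in header")
            index[canon] = header.index(name)

        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            try:
                rec = _parse_row(fields, index, report, lineno)
            except (ValueError, IndexError) as exc:
                report.rows_rejected += 1
                logger.debug("%s:%d rejected: %s", path, lineno, exc)
                continue
            if rec is None:
                continue
            if rec[0] in seen:
                report.duplicates_dropped += 1
                logger.debug("%s:%d duplicate variant_id %s dropped", path, lineno, rec[0])
                continue
            seen.add(rec[0])
            rows.append(rec)

    table = pd.DataFrame(rows, columns=COLUMNS)
    if table.empty:
        table = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            COLUMNS, [str, str, int, str, str, float, float, float, float, float])})
    if trait_id is None:
        trait_id = _strip_suffixes(str(path))
    return GwasSummary(trait_id, trait_type, table, report)


def _strip_suffixes(path: str) -> str:
    import os
    base = os.path.basename(path)
    for suf in (".gz", ".tsv", ".txt"):
        if base.endswith(suf):
            base = base[: -len(suf)]
    return base


def _parse_row(fields, index, report: ValidationReport, lineno: int):
    variant_id = fields[index["variant_id"]].strip()
    chrom = fields[index["chrom"]].strip()
    pos = int(fields[index["pos"]])
    ea = fields[index["ea"]].strip().upper()
    oa = fields[index["oa"]].strip().upper()
    eaf = _parse_float(fields[index["eaf"]])
    beta = _parse_float(fields[index["beta"]])
    se = _parse_float(fields[index["se"]])
    pval = _parse_float(fields[index["pval"]])
    n = _parse_float(fields[index["n"]])

    reasons = _record_violations(variant_id, pos, ea, oa, eaf, beta, se, pval)
    if reasons:
        for r in reasons:
            report.add(r)
        report.rows_rejected += 1
        logger.debug("line %d rejected: %s", lineno, ",".join(reasons))
        return None
    if pval == 0.0:
        logger.warning("line %d: p-value 0 clamped to %.3g", lineno, TINY_P)
        pval = TINY_P
    return (variant_id, chrom, pos, ea, oa, eaf, beta, se, pval, n)


def _record_violations(variant_id, pos, ea, oa, eaf, beta, se, pval) -> list[str]:
    reasons = []
    if not variant_id:
        reasons.append("empty_variant_id")
    if pos < 1:
        reasons.append("position")
    if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
        reasons.append("allele_alphabet")
    elif ea == oa:
        reasons.append("allele_identity")
    if not np.isnan(eaf) and not (0.0 <= eaf <= 1.0):
        reasons.append("eaf_range")
    if np.isnan(beta):
        reasons.append("beta_numeric")
    if np.isnan(se) or se <= 0.0:
        reasons.append("se_positive")
    if np.isnan(pval) or not (0.0 <= pval <= 1.0):
        reasons.append("pval_range")
    return reasons


def write_sumstats(gwas: GwasSummary, path) -> None:
    """Write summary statistics in the default dialect.

    Numeric fields carry 12 significant digits so a write/read round trip
    reproduces betas and standard errors exactly for practical purposes.
    """
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for row in gwas.table.itertuples(index=False):
            eaf = "." if np.isnan(row.eaf) else f"{row.eaf:.12g}"
            n = "." if (isinstance(row.n, float) and np.isnan(row.n)) else f"{row.n:.12g}"
            fh.write(
                f"{row.variant_id}\t{row.chrom}\t{int(row.pos)}\t{row.ea}\t{row.oa}\t"
                f"{eaf}\t{row.beta:.12g}\t{row.se:.12g}\t{row.pval:.12g}\t{n}\n"
            )


def validate(gwas: GwasSummary) -> ValidationReport:
    """Check every record against the type invariants; never raises.

    Returns per-rule violation counts.  A zero-violation report means all
    invariants (se > 0, eaf in [0,1] when present, distinct A/C/G/T alleles,
    pos >= 1, p in (0,1], unique variant ids) hold.
    """
    report = ValidationReport()
    t = gwas.table
    if t.empty:
        return report
    report.add("se_positive", int((~(t["se"] > 0)).sum()))
    eaf = t["eaf"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        report.add("eaf_range", int(((eaf < 0) | (eaf > 1)).sum()))
    ok_alleles = t["ea"].isin(list(_VALID_ALLELES)) & t["oa"].isin(list(_VALID_ALLELES))
    report.add("allele_alphabet", int((~ok_alleles).sum()))
    report.add("allele_identity", int((ok_alleles & (t["ea"] == t["oa"])).sum()))
    report.add("position", int((t["pos"] < 1).sum()))
    pv = t["pval"].to_numpy(dtype=float)
    report.add("pval_range", int((~((pv > 0) & (pv <= 1))).sum()))
    report.add("duplicate_variant_id", int(t["variant_id"].duplicated().sum()))
    return report
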