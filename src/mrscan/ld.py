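"""Genotype reference panels: pairwise LD (r²) and greedy clumping.

A :class:`ReferencePanel` holds alt-allele dosages (one row per biallelic
variant, one column per individual) plus variant metadata.  Panels load from
VCF (hard-call genotypes, via pysam) or from a plain dosage TSV.  LD between
two variants is the squared Pearson correlation of their dosage rows.

Clumping follows the standard greedy procedure used by PLINK-style services:
sort associations by p-value, take the best remaining variant as an index,
discard everything on the same chromosome within the window whose r² with the
index reaches the threshold, repeat.  The conventional stringent setting for
Mendelian-randomization instrument selection is r² < 0.001 within 10,000 kb,
which is the default here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("mrscan")


class PanelError(ValueError):
    """Malformed panel file or unknown variant lookup."""


@dataclass
class ClumpSpec:
    """Clumping parameters: discard r² >= r2_threshold within ±window_kb."""

    r2_threshold: float = 0.001
    window_kb: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass
class ReferencePanel:
    """Dosage matrix with variant metadata for LD computation.

    ``variants`` has columns variant_id, chrom, pos, ref, alt; ``dosages`` is
    an (n_variants, n_individuals) array of alt-allele dosages in [0, 2].
    Monomorphic variants (zero dosage variance) are legal.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.variants) != self.dosages.shape[0]:
            raise ValueError("variants/dosages row mismatch")
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate variant_id in panel")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        self._index = {v: i for i, v in enumerate(ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def row(self, variant_id: str) -> np.ndarray:
        try:
            return self.dosages[self._index[variant_id]]
        except KeyError:
            raise PanelError(f"variant {variant_id!r} not in panel") from None

    def locus(self, variant_id: str) -> tuple[str, int]:
        try:
            i = self._index[variant_id]
        except KeyError:
            raise PanelError(f"variant {variant_id!r} not in panel") from None
        return str(self.variants["chrom"].iat[i]), int(self.variants["pos"].iat[i])


# ---------------------------------------------------------------------------
# loading / writing

_META_COLS = ["variant_id", "chrom", "pos", "ref", "alt"]


def load_panel(path, format: str = "vcf") -> ReferencePanel:
    """Load a reference panel from ``vcf`` or ``dosage_tsv``.

    VCF genotypes are hard calls converted to alt-allele dosage 0/1/2; a
    missing call becomes that variant's mean observed dosage.  Multi-allelic
    records are skipped with a log entry.
    """
    if format == "vcf":
        return _load_vcf(path)
    if format == "dosage_tsv":
        return _load_dosage_tsv(path)
    raise ValueError(f"unknown panel format {format!r}")


def _load_vcf(path) -> ReferencePanel:
    meta: list[tuple] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                n_skipped += 1
                logger.info("skipping non-biallelic-SNP record at %s:%d", rec.chrom, rec.pos)
                continue
            dose = np.empty(len(samples), dtype=float)
            for j, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dose[j] = np.nan
                else:
                    dose[j] = float(sum(1 for a in gt if a != 0))
            if np.isnan(dose).any():
                mean = np.nanmean(dose) if not np.isnan(dose).all() else 0.0
                dose = np.where(np.isnan(dose), mean, dose)
            vid = rec.id if rec.id is not None else f"{rec.chrom}:{rec.pos}"
            meta.append((vid, str(rec.chrom), int(rec.pos), rec.ref, rec.alts[0]))
            rows.append(dose)
    if n_skipped:
        logger.info("%d multi-allelic/non-SNP records skipped", n_skipped)
    variants = pd.DataFrame(meta, columns=_META_COLS)
    dosages = np.vstack(rows) if rows else np.empty((0, 0))
    return ReferencePanel(variants, dosages)


def _load_dosage_tsv(path) -> ReferencePanel:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelError(f"cannot parse dosage TSV {path}: {exc}") from exc
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: dosage TSV lacks columns {missing}")
    sample_cols = [c for c in df.columns if c not in _META_COLS]
    dosages = df[sample_cols].to_numpy(dtype=float)
    return ReferencePanel(df[_META_COLS].reset_index(drop=True), dosages)


def write_dosage_tsv(panel: ReferencePanel, path) -> None:
    """Write a panel in the dosage TSV format read by :func:`load_panel`."""
    samples = [f"S{i+1}" for i in range(panel.n_individuals)]
    df = pd.concat(
        [panel.variants.reset_index(drop=True),
         pd.DataFrame(panel.dosages, columns=samples)],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# LD

def ld_r2(panel: ReferencePanel, a: str, b: str) -> float:
    """Squared Pearson correlation of two variants' dosage rows.

    Returns 0 (with a warning) if either variant is monomorphic in the panel,
    where the correlation is undefined.
    """
    x, y = panel.row(a), panel.row(b)
    return _r2(x, y, warn=f"{a}/{b}")


def _r2(x: np.ndarray, y: np.ndarray, warn: str | None = None) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        if warn:
            logger.warning("monomorphic variant in r² for %s; returning 0", warn)
        return 0.0
    r = float(xc @ yc) / np.sqrt(vx * vy)
    return min(r * r, 1.0)


# ---------------------------------------------------------------------------
# clumping

def clump(
    assocs,
    panel: ReferencePanel,
    spec: ClumpSpec | None = None,
    positions: dict[str, tuple[str, int]] | None = None,
) -> list[str]:
    """Greedy p-value-ordered LD clumping.

    Parameters
    ----------
    assocs:
        Iterable of ``(variant_id, pvalue)`` pairs.
    panel:
        Reference panel supplying dosages (and loci unless ``positions`` is
        given).
    spec:
        Clumping thresholds; defaults to r² < 0.001 within 10,000 kb.
    positions:
        Optional ``variant_id -> (chrom, pos)`` map overriding panel loci.

    Variants absent from the panel are dropped (logged) before clumping —
    without dosages their independence cannot be established.  Ties on p are
    broken lexicographically by variant_id so output is order-invariant.
    """
    spec = spec or ClumpSpec()
    items = [(str(v), float(p)) for v, p in assocs]
    in_panel = [it for it in items if it[0] in panel]
    if len(in_panel) < len(items):
        logger.info("clump: %d variant(s) absent from panel dropped", len(items) - len(in_panel))
    if not in_panel:
        return []

    order = sorted(in_panel, key=lambda it: (it[1], it[0]))
    loci = {v: (positions[v] if positions and v in positions else panel.locus(v))
            for v, _ in order}
    window_bp = spec.window_kb * 1000

    remaining = [v for v, _ in order]
    alive = {v: True for v in remaining}
    retained: list[str] = []
    for idx_var in remaining:
        if not alive[idx_var]:
            continue
        retained.append(idx_var)
        alive[idx_var] = False
        chrom_i, pos_i = loci[idx_var]
        row_i = panel.row(idx_var)
        for other in remaining:
            if not alive[other]:
                continue
            chrom_j, pos_j = loci[other]
            if chrom_j != chrom_i or abs(pos_j - pos_i) > window_bp:
                continue
            if _r2(row_i, panel.row(other)) >= spec.r2_threshold:
                alive[other] = False
    return retained
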