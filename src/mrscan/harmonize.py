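"""Allele harmonization of exposure/outcome effect pairs.

Two GWAS report the same variant relative to possibly different effect
alleles, and possibly on opposite DNA strands.  Harmonization rewrites each
outcome record onto the exposure's effect-allele orientation:

* same orientation — kept as is;
* swapped effect/other allele — outcome beta negated, eaf mirrored (status
  ``flipped``);
* orientation only resolvable after complementing the outcome's alleles to
  the other strand — complemented, then the rules above apply (status
  ``strand_flipped``);
* palindromic variants (A/T or C/G), whose strand is inherently ambiguous,
  are resolved by effect-allele frequency when both frequencies sit clearly
  away from 0.5, and dropped otherwise (status ``dropped_palindromic``);
* anything irreconcilable is ``dropped_mismatch``.

The frequency window for "too close to 0.5" defaults to [0.42, 0.58], the
de-facto standard of common MR tooling; ``strict_palindromic=True`` drops
every palindromic variant regardless of frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SummaryRecord

logger = logging.getLogger("mrscan")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

KEPT = "kept"
FLIPPED = "flipped"
STRAND_FLIPPED = "strand_flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"


def complement_alleles(ea: str, oa: str) -> tuple[str, str]:
    return _COMPLEMENT[ea], _COMPLEMENT[oa]


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T and C/G variants, whose strand cannot be inferred."""
    return _COMPLEMENT.get(ea) == oa


@dataclass
class HarmonizedVariant:
    """One variant's aligned exposure/outcome effects (common effect allele)."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    status: str


@dataclass
class HarmonizedSet:
    """The per-pair MR input: k aligned instrument effect pairs."""

    exposure_id: str
    outcome_id: str
    variants: list[HarmonizedVariant] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.variants)

    def __len__(self) -> int:
        return self.k

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        bx = np.array([v.beta_exp for v in self.variants], dtype=float)
        sx = np.array([v.se_exp for v in self.variants], dtype=float)
        by = np.array([v.beta_out for v in self.variants], dtype=float)
        sy = np.array([v.se_out for v in self.variants], dtype=float)
        return bx, sx, by, sy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v.variant_id, v.beta_exp, v.se_exp, v.beta_out, v.se_out, v.status)
             for v in self.variants],
            columns=["variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "status"],
        )


def _mirror(eaf: float) -> float:
    return np.nan if np.isnan(eaf) else 1.0 - eaf


def harmonize_pair(
    exp: SummaryRecord,
    out: SummaryRecord,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
    strict_palindromic: bool = False,
) -> tuple[HarmonizedVariant | None, str]:
    """Harmonize one exposure/outcome record pair.

    Returns ``(variant, status)``; the variant is None when dropped.
    """
    lo, hi = palindromic_eaf_window
    ea_x, oa_x = exp.ea, exp.oa
    ea_y, oa_y = out.ea, out.oa
    beta_out, eaf_out = out.beta, out.eaf

    if is_palindromic(ea_x, oa_x):
        # Strand is unknowable from alleles alone: {A,T} reads the same on
        # both strands.  Align by which side of 0.5 the frequencies fall on,
        # but only when both are informative and outside the ambiguity window.
        if strict_palindromic:
            return None, DROPPED_PALINDROMIC
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return None, DROPPED_MISMATCH
        if np.isnan(exp.eaf) or np.isnan(out.eaf):
            return None, DROPPED_PALINDROMIC
        if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
            return None, DROPPED_PALINDROMIC
        eaf_y_for_ea_x = out.eaf if ea_y == ea_x else 1.0 - out.eaf
        same_side = (exp.eaf < 0.5) == (eaf_y_for_ea_x < 0.5)
        if ea_y == ea_x:
            status = KEPT if same_side else FLIPPED
        else:
            status = FLIPPED if same_side else KEPT
        if status == FLIPPED:
            beta_out = -beta_out
            eaf_out = _mirror(eaf_out)
        return _make(exp, out, beta_out, eaf_out, status), status

    status: str | None = None
    if (ea_y, oa_y) == (ea_x, oa_x):
        status = KEPT
    elif (ea_y, oa_y) == (oa_x, ea_x):
        status = FLIPPED
        beta_out = -beta_out
        eaf_out = _mirror(eaf_out)
    else:
        cea, coa = complement_alleles(ea_y, oa_y)
        if (cea, coa) == (ea_x, oa_x):
            status = STRAND_FLIPPED
        elif (cea, coa) == (oa_x, ea_x):
            status = STRAND_FLIPPED
            beta_out = -beta_out
            eaf_out = _mirror(eaf_out)
        else:
            return None, DROPPED_MISMATCH
    return _make(exp, out, beta_out, eaf_out, status), status


def _make(exp: SummaryRecord, out: SummaryRecord, beta_out, eaf_out, status) -> HarmonizedVariant:
    return HarmonizedVariant(
        variant_id=exp.variant_id,
        beta_exp=exp.beta, se_exp=exp.se,
        beta_out=float(beta_out), se_out=out.se,
        eaf_exp=exp.eaf, eaf_out=float(eaf_out) if not np.isnan(eaf_out) else np.nan,
        status=status,
    )


def harmonize(
    exp_records,
    out_records,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
    strict_palindromic: bool = False,
) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Harmonize paired exposure/outcome records.

    ``exp_records`` and ``out_records`` are parallel sequences of
    :class:`SummaryRecord` paired by variant_id (same order, same ids).
    Returns the harmonized set (kept/flipped/strand_flipped variants only)
    and an audit table with one row per input variant and its status.
    """
    hset = HarmonizedSet(exposure_id, outcome_id)
    audit_rows = []
    for exp, out in zip(exp_records, out_records, strict=True):
        if exp.variant_id != out.variant_id:
            raise ValueError(
                f"records not paired: {exp.variant_id!r} vs {out.variant_id!r}")
        hv, status = harmonize_pair(
            exp, out, palindromic_eaf_window, strict_palindromic)
        audit_rows.append((exp.variant_id, status))
        if hv is not None:
            hset.variants.append(hv)
        else:
            logger.debug("variant %s dropped during harmonization: %s", exp.variant_id, status)
    audit = pd.DataFrame(audit_rows, columns=["variant_id", "status"])
    return hset, audit
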