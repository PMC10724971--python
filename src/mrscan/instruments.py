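"""Instrument selection for one exposure–outcome pair.

The selection pipeline keeps, in order:

1. exposure variants at genome-wide significance (p < 5e-8 by default);
2. the LD-clumped subset of those (r² < 0.001 within 10,000 kb);
3. variants present in the outcome GWAS whose allele pair matches the
   exposure's as a set, directly or after strand complement (orientation is
   resolved later by harmonization);
4. variants with per-SNP instrument strength F = (beta/se)² ≥ 10;
5. variants with no direct genome-wide-significant outcome association
   (outcome p > 5e-8).

Attrition is recorded step by step so the fate of every input variant is
auditable.  An empty final set is a legal outcome — the exposure simply has
no usable instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .harmonize import complement_alleles
from .ld import ClumpSpec, ReferencePanel, clump
from .sumstats import GwasSummary

STEPS = ("exposure_p", "clump", "outcome_match", "f_stat", "outcome_p")


class DomainError(ValueError):
    """Invalid argument for a statistical primitive."""


@dataclass
class SelectionConfig:
    """Thresholds of the four-step instrument filter."""

    exposure_p_threshold: float = 5e-8
    clump: ClumpSpec = field(default_factory=ClumpSpec)
    min_f: float = 10.0
    outcome_p_exclusion: float = 5e-8

    def __post_init__(self) -> None:
        for name in ("exposure_p_threshold", "outcome_p_exclusion"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_f <= 0:
            raise ValueError("min_f must be positive")


@dataclass
class InstrumentSet:
    """Variants retained as instruments for one exposure, with audit trail."""

    exposure_id: str
    variant_ids: list[str]
    f_stats: dict[str, float]
    selection_log: dict[str, int]  # step name -> count dropped at that step

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.exposure_id, v, self.f_stats[v]) for v in self.variant_ids],
            columns=["exposure_id", "variant_id", "F"],
        )


def f_statistic(beta: float, se: float) -> float:
    """Per-SNP instrument-strength F statistic, the squared z-score (beta/se)²."""
    if se <= 0:
        raise DomainError(f"se must be positive, got {se}")
    z = beta / se
    return z * z


def _alleles_match(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> bool:
    """Set equality of allele pairs, directly or via strand complement."""
    want = {ea_x, oa_x}
    if {ea_y, oa_y} == want:
        return True
    try:
        cea, coa = complement_alleles(ea_y, oa_y)
    except KeyError:
        return False
    return {cea, coa} == want


def select_instruments(
    exposure: GwasSummary,
    outcome: GwasSummary,
    panel: ReferencePanel,
    cfg: SelectionConfig | None = None,
) -> InstrumentSet:
    """Run the full instrument-selection pipeline for one exposure."""
    cfg = cfg or SelectionConfig()
    exp = exposure.table
    log: dict[str, int] = {}

    # (a) genome-wide-significant exposure associations
    sig = exp[exp["pval"] < cfg.exposure_p_threshold]
    log["exposure_p"] = len(exp) - len(sig)

    # (b) LD clumping (variants absent from the panel are dropped here too)
    retained = clump(
        list(zip(sig["variant_id"], sig["pval"])), panel, cfg.clump)
    log["clump"] = len(sig) - len(retained)
    sig = sig[sig["variant_id"].isin(set(retained))]

    # (c) present in outcome with a compatible allele pair
    out = outcome.table.set_index("variant_id")
    matched_ids = []
    for row in sig.itertuples(index=False):
        if row.variant_id not in out.index:
            continue
        o = out.loc[row.variant_id]
        if _alleles_match(row.ea, row.oa, str(o["ea"]), str(o["oa"])):
            matched_ids.append(row.variant_id)
    log["outcome_match"] = len(sig) - len(matched_ids)
    sig = sig[sig["variant_id"].isin(set(matched_ids))]

    # (d) per-SNP instrument strength
    fvals = {r.variant_id: f_statistic(r.beta, r.se) for r in sig.itertuples(index=False)}
    strong = [v for v in sig["variant_id"] if fvals[v] >= cfg.min_f]
    log["f_stat"] = len(sig) - len(strong)
    sig = sig[sig["variant_id"].isin(set(strong))]

    # (e) no direct genome-wide-significant outcome association
    final = [v for v in sig["variant_id"]
             if float(out.loc[v, "pval"]) > cfg.outcome_p_exclusion]
    log["outcome_p"] = len(sig) - len(final)

    return InstrumentSet(
        exposure_id=exposure.trait_id,
        variant_ids=list(final),
        f_stats={v: fvals[v] for v in final},
        selection_log=log,
    )
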