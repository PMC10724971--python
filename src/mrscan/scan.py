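"""Metabolome-wide forward and reverse MR scans.

For each exposure–outcome pair the pipeline selects instruments, harmonizes
alleles, and estimates the causal effect with the Wald ratio (one
instrument) or IVW (two or more).  Heterogeneity (Cochran's Q) attaches at
k ≥ 2; the sensitivity estimators — MR-Egger, weighted median, maximum
likelihood — attach at k ≥ 3, the smallest k at which the Egger intercept
model has residual degrees of freedom.

Multiplicity is controlled family-wise by Bonferroni.  Forward scans divide
alpha by the number of exposures actually tested (those with at least one
surviving instrument), so the denominator is data-dependent; reverse scans
default to the full trait-pair count (every blood-pressure trait times every
metabolite), overridable through the config.  Significance is strict:
p < alpha/n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from .harmonize import HarmonizedSet, harmonize
from .instruments import SelectionConfig, select_instruments
from .ld import ReferencePanel
from .sumstats import GwasSummary

logger = logging.getLogger("mrscan")


@dataclass
class ScanConfig:
    """Scan-level settings wrapping the per-pair selection thresholds."""

    alpha: float = 0.05
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    reverse_n_tests_override: int | None = None
    seed: int = 0
    n_boot: int = 1000          # weighted-median bootstrap replicates
    secondary_min_k: int = 3
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ScanResult:
    """Per-pair MR results of one scan direction.

    ``table`` has one row per tested pair; ``exclusions`` lists pairs with
    no surviving instruments and the step-by-step attrition that emptied
    them.  ``n_tested`` counts tested exposures and equals the row count.
    """

    outcome_id: str
    n_tested: int
    threshold: float
    table: pd.DataFrame
    exclusions: pd.DataFrame

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


_RESULT_COLUMNS = [
    "exposure_id", "outcome_id", "k", "method", "beta", "se", "pvalue",
    "or_point", "or_low", "or_high",
    "Q", "Q_df", "Q_pvalue",
    "egger_beta", "egger_se", "egger_pvalue",
    "egger_intercept", "egger_intercept_se", "egger_intercept_pvalue",
    "wm_beta", "wm_se", "wm_pvalue",
    "ml_beta", "ml_se", "ml_pvalue",
    "significant", "direction",
]


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha/n_tests."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def harmonize_instruments(
    exposure: GwasSummary,
    outcome: GwasSummary,
    variant_ids,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Harmonized exposure/outcome effect pairs for the given variants."""
    order = [v for v in exposure.table["variant_id"] if v in set(variant_ids)]
    exp_recs = [exposure.get(v) for v in order]
    out_recs = [outcome.get(v) for v in order]
    hset, _ = harmonize(
        exp_recs, out_recs,
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
        palindromic_eaf_window=palindromic_eaf_window,
    )
    return hset


def _estimate_pair(h: HarmonizedSet, cfg: ScanConfig, wm_seed: int) -> dict:
    """All estimators k permits, as one flat result-row dict."""
    row: dict = {c: np.nan for c in _RESULT_COLUMNS}
    row.update(exposure_id=h.exposure_id, outcome_id=h.outcome_id, k=h.k)
    primary = est.wald_ratio(h) if h.k == 1 else est.ivw(h)
    row.update(method=primary.method, beta=primary.beta, se=primary.se,
               pvalue=primary.pvalue, or_point=primary.or_point,
               or_low=primary.or_low, or_high=primary.or_high)
    if h.k >= 2:
        het = est.cochran_q(h)
        row.update(Q=het.Q, Q_df=het.df, Q_pvalue=het.pvalue)
    if h.k >= cfg.secondary_min_k:
        eg = est.egger(h)
        row.update(egger_beta=eg.slope.beta, egger_se=eg.slope.se,
                   egger_pvalue=eg.slope.pvalue,
                   egger_intercept=eg.intercept,
                   egger_intercept_se=eg.intercept_se,
                   egger_intercept_pvalue=eg.intercept_pvalue)
        wm = est.weighted_median(h, n_boot=cfg.n_boot, seed=wm_seed)
        row.update(wm_beta=wm.beta, wm_se=wm.se, wm_pvalue=wm.pvalue)
        ml = est.max_likelihood(h)
        row.update(ml_beta=ml.beta, ml_se=ml.se, ml_pvalue=ml.pvalue)
    row["direction"] = "positive" if row["beta"] > 0 else "negative"
    return row


def _wm_seed(cfg_seed: int, i: int) -> int:
    # deterministic per-pair bootstrap seed, independent of scan composition
    return int(np.random.SeedSequence([int(cfg_seed), 7, i]).generate_state(1)[0] % (2**31))


def _run_pairs(pairs, panel: ReferencePanel, cfg: ScanConfig):
    rows: list[dict] = []
    excl: list[tuple] = []
    for i, (exposure, outcome) in enumerate(pairs):
        sel = select_instruments(exposure, outcome, panel, cfg.selection)
        if sel.k == 0:
            excl.append((exposure.trait_id, outcome.trait_id, "no_instruments",
                         _fmt_log(sel.selection_log)))
            continue
        h = harmonize_instruments(exposure, outcome, sel.variant_ids,
                                  cfg.palindromic_eaf_window)
        if h.k == 0:
            excl.append((exposure.trait_id, outcome.trait_id, "all_dropped_in_harmonization",
                         _fmt_log(sel.selection_log)))
            continue
        rows.append(_estimate_pair(h, cfg, _wm_seed(cfg.seed, i)))
    table = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    exclusions = pd.DataFrame(
        excl, columns=["exposure_id", "outcome_id", "reason", "selection_log"])
    return table, exclusions


def _fmt_log(log: dict[str, int]) -> str:
    return ";".join(f"{k}={v}" for k, v in log.items())


def _finalize(table: pd.DataFrame, exclusions: pd.DataFrame, outcome_id: str,
              threshold: float) -> ScanResult:
    table = table.copy()
    table["significant"] = table["pvalue"] < threshold
    return ScanResult(
        outcome_id=outcome_id, n_tested=len(table),
        threshold=threshold, table=table, exclusions=exclusions,
    )


def run_forward_scan(
    exposures: list[GwasSummary],
    outcome: GwasSummary,
    panel: ReferencePanel,
    cfg: ScanConfig | None = None,
) -> ScanResult:
    """Metabolome-wide forward scan: every exposure against one outcome.

    The Bonferroni denominator is the number of exposures with at least one
    surviving instrument; exposures with none are excluded (and audited)
    rather than counted as tests.
    """
    cfg = cfg or ScanConfig()
    table, exclusions = _run_pairs(
        ((e, outcome) for e in exposures), panel, cfg)
    n = max(len(table), 1)
    threshold = bonferroni_threshold(n, cfg.alpha)
    result = _finalize(table, exclusions, outcome.trait_id, threshold)
    logger.info("forward scan vs %s: %d/%d tested, threshold %.3g, %d significant",
                outcome.trait_id, result.n_tested, len(exposures), threshold,
                int(result.table["significant"].sum()))
    return result


def run_reverse_scan(
    bp_traits: list[GwasSummary],
    metabolites: list[GwasSummary],
    panel: ReferencePanel,
    cfg: ScanConfig | None = None,
) -> ScanResult:
    """Reverse scan: blood-pressure traits as exposures, metabolites as outcomes.

    Identical machinery with the roles swapped.  The Bonferroni denominator
    defaults to the full pair count len(bp_traits) × len(metabolites) — the
    conventional conservative choice when the tested count varies per trait —
    unless ``cfg.reverse_n_tests_override`` is set.
    """
    cfg = cfg or ScanConfig()
    if not metabolites:
        empty = pd.DataFrame(columns=_RESULT_COLUMNS)
        excl = pd.DataFrame(columns=["exposure_id", "outcome_id", "reason", "selection_log"])
        return _finalize(empty, excl, "reverse", cfg.alpha)
    pairs = ((bp, met) for bp in bp_traits for met in metabolites)
    table, exclusions = _run_pairs(pairs, panel, cfg)
    n_tests = cfg.reverse_n_tests_override or (len(bp_traits) * len(metabolites))
    threshold = bonferroni_threshold(n_tests, cfg.alpha)
    result = _finalize(table, exclusions, "reverse", threshold)
    logger.info("reverse scan: %d pairs tested, threshold %.3g, %d significant",
                result.n_tested, threshold, int(result.table["significant"].sum()))
    return result


def bidirectional_table(forward: ScanResult, reverse: ScanResult) -> pd.DataFrame:
    """Pair forward and reverse p-values per metabolite (for -log10/-log10 plots).

    Rows cover metabolites testable in both directions: as an exposure in the
    forward scan and as an outcome (of the forward scan's outcome trait) in
    the reverse scan.
    """
    fwd = forward.table[["exposure_id", "pvalue", "significant"]].rename(
        columns={"exposure_id": "metabolite", "pvalue": "forward_pvalue",
                 "significant": "forward_significant"})
    rev = reverse.table
    rev = rev[rev["exposure_id"] == forward.outcome_id] if len(rev) else rev
    rev = rev[["outcome_id", "pvalue", "significant"]].rename(
        columns={"outcome_id": "metabolite", "pvalue": "reverse_pvalue",
                 "significant": "reverse_significant"})
    return fwd.merge(rev, on="metabolite", how="inner")


def volcano_table(scan: ScanResult) -> pd.DataFrame:
    """One row per tested exposure: effect, p, sign and significance flag."""
    t = scan.table
    return pd.DataFrame({
        "exposure_id": t["exposure_id"],
        "beta": t["beta"],
        "pvalue": t["pvalue"],
        "direction": t["direction"],
        "significant": t["significant"],
    }).reset_index(drop=True)
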