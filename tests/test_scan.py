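import numpy as np
import pandas as pd
import pytest

import mrscan as M
from mrscan.scan import (
    ScanConfig,
    bidirectional_table,
    bonferroni_threshold,
    run_forward_scan,
    run_reverse_scan,
    volcano_table,
)
from mrscan.simulate import SimConfig, simulate_metabolome, simulate_panel, simulate_two_sample

# theta tuned so planted per-SNP outcome associations stay clear of the
# 5e-8 exclusion step (z ~ 4) while the pooled IVW signal is overwhelming
SCAN_SIM = SimConfig(m_snps=200, n_blocks=40, n_ref=200, n_exp=2000, n_out=4000,
                     k_causal=4, exposure_h2=0.4, n_metabolites=12,
                     n_causal_metabolites=2, theta_causal=0.2,
                     frac_no_instruments=0.25)


@pytest.fixture(scope="module")
def scan_world():
    exps, out, truth = simulate_metabolome(SCAN_SIM, 8)
    panel = simulate_panel(SCAN_SIM, 8)
    return exps, out, truth, panel


@pytest.fixture(scope="module")
def forward(scan_world):
    exps, out, truth, panel = scan_world
    return run_forward_scan(exps, out, panel, ScanConfig(seed=8))


def test_bonferroni_threshold_values():
    assert bonferroni_threshold(1, 0.05) == 0.05
    assert bonferroni_threshold(703, 0.05) == pytest.approx(0.05 / 703)
    with pytest.raises(ValueError):
        bonferroni_threshold(0, 0.05)
    with pytest.raises(ValueError):
        bonferroni_threshold(10, 1.5)


def test_forward_scan_counts_and_threshold(forward, scan_world):
    exps, out, truth, panel = scan_world
    assert forward.n_tested == len(forward.table)
    assert forward.n_tested == len(truth.expected_tested)
    assert forward.threshold == pytest.approx(0.05 / forward.n_tested)
    excluded = set(forward.exclusions["exposure_id"])
    assert set(truth.no_instrument_traits) <= excluded
    assert forward.n_tested + len(excluded) == len(exps)


def test_forward_scan_flags_planted_traits(forward, scan_world):
    exps, out, truth, panel = scan_world
    flagged = set(forward.significant()["exposure_id"])
    planted = {m for m, v in truth.theta.items() if v != 0}
    assert flagged == planted
    # direction follows the sign of the planted effect
    for m in planted:
        row = forward.table[forward.table["exposure_id"] == m].iloc[0]
        assert row["direction"] == ("positive" if truth.theta[m] > 0 else "negative")


def test_forward_scan_attaches_diagnostics_by_k(forward):
    t = forward.table
    assert (t.loc[t["k"] == 1, "method"] == "wald_ratio").all()
    assert (t.loc[t["k"] >= 2, "method"] == "ivw").all()
    assert t.loc[t["k"] >= 2, "Q"].notna().all()
    assert t.loc[t["k"] >= 3, "egger_intercept"].notna().all()
    assert t.loc[t["k"] >= 3, "wm_beta"].notna().all()
    assert t.loc[t["k"] >= 3, "ml_beta"].notna().all()
    assert t.loc[t["k"] < 3, "egger_intercept"].isna().all()


def test_single_exposure_scan_reproduces_standalone_estimates(scan_world):
    exps, out, truth, panel = scan_world
    target = truth.expected_tested[0]
    gw = next(e for e in exps if e.trait_id == target)
    res = run_forward_scan([gw], out, panel, ScanConfig(seed=8))
    assert res.n_tested == 1
    row = res.table.iloc[0]
    sel = M.select_instruments(gw, out, panel)
    h = M.harmonize_instruments(gw, out, sel.variant_ids)
    ref = M.wald_ratio(h) if h.k == 1 else M.ivw(h)
    assert row["beta"] == pytest.approx(ref.beta, abs=1e-12)
    assert row["pvalue"] == pytest.approx(ref.pvalue, abs=1e-12)
    assert res.threshold == 0.05  # n_tested = 1


def test_scan_deterministic(scan_world):
    exps, out, truth, panel = scan_world
    a = run_forward_scan(exps[:4], out, panel, ScanConfig(seed=8))
    b = run_forward_scan(exps[:4], out, panel, ScanConfig(seed=8))
    pd.testing.assert_frame_equal(a.table, b.table)


def test_significant_set_shrinks_as_alpha_decreases(scan_world):
    exps, out, truth, panel = scan_world
    loose = run_forward_scan(exps, out, panel, ScanConfig(alpha=0.05, seed=8))
    strict = run_forward_scan(exps, out, panel, ScanConfig(alpha=0.001, seed=8))
    assert set(strict.significant()["exposure_id"]) <= set(loose.significant()["exposure_id"])


def test_volcano_table(forward):
    v = volcano_table(forward)
    assert len(v) == forward.n_tested
    assert set(v.columns) == {"exposure_id", "beta", "pvalue", "direction", "significant"}
    assert (v["direction"] == np.where(v["beta"] > 0, "positive", "negative")).all()
    # strict inequality at the boundary
    fake = forward.table.copy()
    fake.loc[fake.index[0], "pvalue"] = forward.threshold
    boundary = M.ScanResult(forward.outcome_id, forward.n_tested, forward.threshold,
                            fake, forward.exclusions)
    boundary.table["significant"] = boundary.table["pvalue"] < boundary.threshold
    assert not volcano_table(boundary).iloc[0]["significant"]


def test_reverse_scan_threshold_uses_full_pair_count(scan_world):
    exps, out, truth, panel = scan_world
    rev = run_reverse_scan([out], exps[:6], panel, ScanConfig(seed=8))
    assert rev.threshold == pytest.approx(0.05 / 6)
    over = run_reverse_scan([out], exps[:6], panel,
                            ScanConfig(seed=8, reverse_n_tests_override=2182))
    assert f"{over.threshold:.2e}" == "2.29e-05"


def test_reverse_scan_empty_metabolites(scan_world):
    exps, out, truth, panel = scan_world
    rev = run_reverse_scan([out], [], panel, ScanConfig(seed=8))
    assert rev.n_tested == 0 and len(rev.table) == 0


def test_directionality_recovered(scan_world):
    """Forward detects the planted metabolite -> BP effects; the reverse
    direction (BP as exposure, metabolites simulated strictly upstream) finds
    nothing significant."""
    exps, out, truth, panel = scan_world
    fwd = run_forward_scan(exps, out, panel, ScanConfig(seed=8))
    rev = run_reverse_scan([out], exps, panel, ScanConfig(seed=8))
    planted = {m for m, v in truth.theta.items() if v != 0}
    assert set(fwd.significant()["exposure_id"]) == planted
    assert len(rev.significant()) == 0


def test_bidirectional_table(forward, scan_world):
    exps, out, truth, panel = scan_world
    rev = run_reverse_scan([out], exps, panel, ScanConfig(seed=8))
    bi = bidirectional_table(forward, rev)
    # one row per metabolite testable in both directions
    both = set(forward.table["exposure_id"]) & set(rev.table["outcome_id"])
    assert set(bi["metabolite"]) == both
    assert not bi["reverse_significant"].any()
    # a reverse scan that tested nothing gives disjoint sets -> empty table
    empty_rev = M.ScanResult("reverse", 0, 0.05, rev.table.iloc[0:0], rev.exclusions)
    assert bidirectional_table(forward, empty_rev).empty
    # identical scans in both roles give a symmetric table
    fake_rev = M.ScanResult("reverse", forward.n_tested, forward.threshold,
                            forward.table.assign(
                                outcome_id=forward.table["exposure_id"],
                                exposure_id=forward.outcome_id),
                            forward.exclusions)
    bi2 = bidirectional_table(forward, fake_rev)
    assert len(bi2) == forward.n_tested
    assert np.allclose(bi2["forward_pvalue"], bi2["reverse_pvalue"])
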