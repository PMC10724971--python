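import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

import mrscan.estimators as est
from mrscan.estimators import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    cochran_q,
    egger,
    ivw,
    max_likelihood,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)

from conftest import harmonized_from_arrays, make_harmonized


# --- Wald ratio ------------------------------------------------------------

@pytest.mark.parametrize("bx,by,sy,beta,se", [
    (1.0, 0.5, 0.1, 0.5, 0.1),
    (2.0, 1.0, 0.2, 0.5, 0.1),
    (-1.0, 0.5, 0.1, -0.5, 0.1),
])
def test_wald_ratio_values(bx, by, sy, beta, se):
    h = harmonized_from_arrays([bx], [0.01], [by], [sy])
    r = wald_ratio(h)
    assert r.beta == pytest.approx(beta)
    assert r.se == pytest.approx(se)
    assert r.pvalue == pytest.approx(2 * stats.norm.sf(abs(beta) / se))


def test_wald_ratio_guards():
    with pytest.raises(DegenerateInstrumentError):
        wald_ratio(harmonized_from_arrays([0.0], [0.01], [0.5], [0.1]))
    with pytest.raises(InsufficientInstrumentsError):
        wald_ratio(make_harmonized(np.random.default_rng(0), 3))


# --- IVW -------------------------------------------------------------------

def test_ivw_symmetric_average_fixed_se():
    h = harmonized_from_arrays([1, 1], [0.01, 0.01], [0.4, 0.6], [0.1, 0.1])
    r = ivw(h, model="fixed")
    assert r.beta == pytest.approx(0.5)
    assert r.se == pytest.approx(0.1 / np.sqrt(2))


def test_ivw_perfect_fit_q_zero(rng):
    bx = rng.normal(0.2, 0.05, 6)
    h = harmonized_from_arrays(bx, np.full(6, 0.01), 0.7 * bx, np.full(6, 0.05))
    assert ivw(h).beta == pytest.approx(0.7)
    het = cochran_q(h)
    assert het.Q == pytest.approx(0.0, abs=1e-20)
    assert het.pvalue == pytest.approx(1.0)
    # random-effects scale is floored at 1: se equals fixed here
    assert ivw(h).se == pytest.approx(ivw(h, model="fixed").se)


def test_ivw_guard():
    with pytest.raises(InsufficientInstrumentsError):
        ivw(harmonized_from_arrays([1.0], [0.01], [0.5], [0.1]))


def _wls_origin_oracle(h):
    bx, _, by, sy = h.arrays()
    res = sm.WLS(by, bx, weights=sy ** -2.0).fit()
    return float(res.params[0]), float(res.bse[0] / np.sqrt(res.scale))


def test_ivw_matches_wls_oracle(rng):
    for _ in range(20):
        h = make_harmonized(rng, int(rng.integers(2, 30)))
        beta_o, se_o = _wls_origin_oracle(h)
        r = ivw(h, model="fixed")
        assert r.beta == pytest.approx(beta_o, abs=1e-10)
        assert r.se == pytest.approx(se_o, abs=1e-10)


# --- Cochran's Q -----------------------------------------------------------

def test_cochran_q_hand_computed():
    # ratios 0.4 and 0.6 with weights 100 around theta = 0.5 -> Q = 2, df = 1
    h = harmonized_from_arrays([1, 1], [0.01, 0.01], [0.4, 0.6], [0.1, 0.1])
    het = cochran_q(h)
    assert het.Q == pytest.approx(2.0)
    assert het.df == 1
    assert het.pvalue == pytest.approx(stats.chi2.sf(2.0, 1))
    assert het.pvalue == pytest.approx(0.15729920, abs=1e-7)


def test_cochran_q_degenerate_guard():
    h = harmonized_from_arrays([1, 0.0], [0.01, 0.01], [0.4, 0.6], [0.1, 0.1])
    with pytest.raises(DegenerateInstrumentError):
        cochran_q(h)


# --- Egger -----------------------------------------------------------------

def test_egger_exact_lines():
    h = harmonized_from_arrays([1, 2, 3], [0.01] * 3, [1, 2, 3], [1, 1, 1])
    r = egger(h)
    assert r.slope.beta == pytest.approx(1.0)
    assert r.intercept == pytest.approx(0.0, abs=1e-12)
    h2 = harmonized_from_arrays([1, 2, 3], [0.01] * 3, [1.5, 2.5, 3.5], [1, 1, 1])
    r2 = egger(h2)
    assert r2.slope.beta == pytest.approx(1.0)
    assert r2.intercept == pytest.approx(0.5)


def test_egger_matches_wls_oracle(rng):
    for _ in range(20):
        h = make_harmonized(rng, int(rng.integers(3, 30)))
        bx, _, by, sy = h.arrays()
        sign = np.where(bx < 0, -1.0, 1.0)
        res = sm.WLS(by * sign, sm.add_constant(bx * sign), weights=sy ** -2.0).fit()
        r = egger(h)
        assert r.intercept == pytest.approx(res.params[0], abs=1e-10)
        assert r.slope.beta == pytest.approx(res.params[1], abs=1e-10)
        # our residual scale is floored at 1 (multiplicative random effects)
        factor = np.sqrt(max(1.0, res.scale) / res.scale)
        assert r.intercept_se == pytest.approx(res.bse[0] * factor, abs=1e-10)
        assert r.slope.se == pytest.approx(res.bse[1] * factor, abs=1e-10)


def test_egger_requires_three_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        egger(harmonized_from_arrays([1, 2], [0.01] * 2, [1, 2], [1, 1]))


# --- weighted median -------------------------------------------------------

def test_weighted_median_middle_value():
    # equal weights, ratios 0.2 / 0.5 / 0.8 -> the middle one
    h = harmonized_from_arrays([1, 1, 1], [0.01] * 3, [0.2, 0.5, 0.8], [0.1] * 3)
    assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(0.5)


def test_weighted_median_interpolation():
    # equal weights, ratios 1..4: S = (.125,.375,.625,.875) -> midpoint of 2,3
    h = harmonized_from_arrays([1] * 4, [0.01] * 4, [1, 2, 3, 4], [0.1] * 4)
    r = weighted_median(h, n_boot=50, seed=1)
    assert r.beta == pytest.approx(2.5)
    # brute-force interpolation oracle
    w = np.full(4, 0.25)
    s = np.cumsum(w) - w / 2
    assert np.interp(0.5, s, [1, 2, 3, 4]) == pytest.approx(2.5)


def test_weighted_median_order_invariant_and_seeded(rng):
    h = make_harmonized(rng, 9)
    perm = list(np.random.default_rng(3).permutation(9))
    h_perm = harmonized_from_arrays(*(arr[perm] for arr in h.arrays()))
    a = weighted_median(h, n_boot=200, seed=42)
    b = weighted_median(h_perm, n_boot=200, seed=42)
    assert a.beta == pytest.approx(b.beta, abs=1e-12)
    assert a.se == pytest.approx(weighted_median(h, n_boot=200, seed=42).se)


# --- maximum likelihood ----------------------------------------------------

def test_max_likelihood_reduces_to_ivw_when_exposure_exact(rng):
    h = make_harmonized(rng, 12)
    for v in h.variants:
        v.se_exp = 1e-8
    ml = max_likelihood(h)
    fixed = ivw(h, model="fixed")
    assert ml.beta == pytest.approx(fixed.beta, rel=1e-4)
    assert ml.se == pytest.approx(fixed.se, rel=1e-3)


def test_max_likelihood_perfect_proportionality(rng):
    bx = rng.normal(0.2, 0.05, 8)
    h = harmonized_from_arrays(bx, np.full(8, 0.01), 0.4 * bx, np.full(8, 0.05))
    assert max_likelihood(h).beta == pytest.approx(0.4, abs=1e-8)


def test_max_likelihood_is_a_local_optimum(rng):
    h = make_harmonized(rng, 15)
    bx, sx, by, sy = h.arrays()
    theta = max_likelihood(h).beta
    xi = (bx / sx**2 + theta * by / sy**2) / (1 / sx**2 + theta**2 / sy**2)

    def negll(t, x):
        return 0.5 * np.sum((bx - x) ** 2 / sx**2) + 0.5 * np.sum((by - t * x) ** 2 / sy**2)

    best = negll(theta, xi)
    for _ in range(100):
        t = theta + rng.normal(0, 0.02)
        x = xi + rng.normal(0, 0.002, xi.shape)
        assert negll(t, x) >= best - 1e-9


# --- OR scale and shared invariants ---------------------------------------

def test_to_odds_ratio():
    se = 0.1
    orp, orl, orh = to_odds_ratio(0.0, se)
    assert orp == 1.0
    assert orl == pytest.approx(np.exp(-1.959964 * se))
    assert orh == pytest.approx(np.exp(1.959964 * se))
    assert to_odds_ratio(np.log(2), 0.3)[0] == pytest.approx(2.0)


@given(seed=st.integers(0, 10_000))
@settings(deadline=None, max_examples=30, derandomize=True)
def test_or_bounds_symmetric_on_log_scale(seed):
    rng = np.random.default_rng(seed)
    beta, se = float(rng.normal()), float(rng.uniform(0.01, 1))
    orp, orl, orh = to_odds_ratio(beta, se)
    assert orl <= orp <= orh
    assert np.log(orp) - np.log(orl) == pytest.approx(np.log(orh) - np.log(orp), abs=1e-12)


@given(seed=st.integers(0, 10_000))
@settings(deadline=None, max_examples=25, derandomize=True)
def test_estimators_equivariant_under_global_sign_flip(seed):
    """Recoding every instrument to the other allele (which negates both
    betas of each pair) leaves every ratio, hence every estimate, unchanged."""
    rng = np.random.default_rng(seed)
    h = make_harmonized(rng, 8)
    bx, sx, by, sy = h.arrays()
    h_flip = harmonized_from_arrays(-bx, sx, -by, sy)
    assert ivw(h_flip).beta == pytest.approx(ivw(h).beta, abs=1e-12)
    assert ivw(h_flip).se == pytest.approx(ivw(h).se, abs=1e-12)
    assert egger(h_flip).slope.beta == pytest.approx(egger(h).slope.beta, abs=1e-12)
    assert egger(h_flip).intercept == pytest.approx(egger(h).intercept, abs=1e-12)
    assert cochran_q(h_flip).Q == pytest.approx(cochran_q(h).Q, abs=1e-9)
    wm_a = weighted_median(h, n_boot=10, seed=0).beta
    wm_b = weighted_median(h_flip, n_boot=10, seed=0).beta
    assert wm_b == pytest.approx(wm_a, abs=1e-12)
    assert max_likelihood(h_flip).beta == pytest.approx(max_likelihood(h).beta, abs=1e-8)
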