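"""Causal-effect estimators and diagnostics for two-sample MR.

All estimators consume a :class:`~mrscan.harmonize.HarmonizedSet` of k
aligned per-variant effect pairs (β_Xj, σ_Xj, β_Yj, σ_Yj) and return the
causal effect of a 1-SD change in the exposure on the outcome:

* Wald ratio — β_Y/β_X for a single instrument; SE by the first-order delta
  method σ_Y/|β_X|.
* IVW — inverse-variance-weighted combination of per-instrument ratios,
  algebraically a weighted regression of β_Y on β_X through the origin with
  weights σ_Y⁻².  The default multiplicative random-effects model inflates
  the fixed-effect SE by max(1, √(Q/(k−1))), so it reduces to the
  fixed-effect model when there is no excess heterogeneity.
* Cochran's Q — heterogeneity of the per-instrument ratios about the IVW
  estimate, referred to χ²(k−1).
* MR-Egger — the same weighted regression with a free intercept; a nonzero
  intercept indicates directional horizontal pleiotropy.  Inference uses
  t(k−2), so k ≥ 3 is required.
* Weighted median — consistent when instruments carrying at least half the
  weight are valid; SE by seeded parametric bootstrap.
* Maximum likelihood — joint normal likelihood over the causal effect and
  the k unknown true SNP–exposure effects, accounting for uncertainty in
  both sets of betas.

Odds-ratio presentation uses exp(β) with 95% limits exp(β ± 1.959964·σ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .harmonize import HarmonizedSet

Z_95 = 1.959964  # two-sided 95% normal quantile as conventionally printed


class DegenerateInstrumentError(ValueError):
    """An instrument with zero exposure effect makes ratio estimates undefined."""


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator's minimum k."""


class EstimationError(RuntimeError):
    """Numerical optimization failed; carries solver diagnostics."""


@dataclass
class MREstimate:
    """A causal-effect estimate with normal/t-based inference and OR scale."""

    method: str
    k: int
    beta: float
    se: float
    pvalue: float
    or_point: float
    or_low: float
    or_high: float


@dataclass
class HetTest:
    """Cochran's Q heterogeneity test against χ²(df)."""

    Q: float
    df: int
    pvalue: float


@dataclass
class EggerResult:
    """MR-Egger slope estimate plus the pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """(OR, 95% lower, 95% upper) = exp(beta), exp(beta ∓ 1.959964·se)."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return float(np.exp(beta)), float(np.exp(beta - Z_95 * se)), float(np.exp(beta + Z_95 * se))


def _normal_p(beta: float, se: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(beta / se))))


def _t_p(beta: float, se: float, df: int) -> float:
    return float(min(1.0, 2.0 * stats.t.sf(abs(beta / se), df)))


def _estimate(method: str, k: int, beta: float, se: float, pvalue: float) -> MREstimate:
    orp, orl, orh = to_odds_ratio(beta, se)
    return MREstimate(method, k, float(beta), float(se), float(pvalue), orp, orl, orh)


def _check_bx(bx: np.ndarray) -> None:
    if np.any(bx == 0.0):
        raise DegenerateInstrumentError("instrument with beta_exp == 0")


# ---------------------------------------------------------------------------

def wald_ratio(h: HarmonizedSet) -> MREstimate:
    """Single-instrument causal estimate β_Y/β_X (delta-method SE σ_Y/|β_X|)."""
    if h.k != 1:
        raise InsufficientInstrumentsError(f"wald_ratio requires k = 1, got k = {h.k}")
    bx, _, by, sy = h.arrays()
    _check_bx(bx)
    beta = float(by[0] / bx[0])
    se = float(sy[0] / abs(bx[0]))
    return _estimate("wald_ratio", 1, beta, se, _normal_p(beta, se))


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate over k ≥ 2 instruments.

    ``model="fixed"`` gives the classical fixed-effect SE; the default
    ``"multiplicative_random"`` inflates it by max(1, √(Q/(k−1))).
    """
    if h.k < 2:
        raise InsufficientInstrumentsError(
            f"ivw requires k >= 2 (got k = {h.k}); use wald_ratio for a single instrument")
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, _, by, sy = h.arrays()
    _check_bx(bx)
    w = sy ** -2.0
    swx2 = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / swx2
    se = swx2 ** -0.5
    if model == "multiplicative_random":
        q = _q_statistic(bx, by, sy, beta)
        se *= max(1.0, np.sqrt(q / (h.k - 1)))
    return _estimate("ivw", h.k, beta, se, _normal_p(beta, se))


def _q_statistic(bx, by, sy, theta_ivw: float) -> float:
    ratios = by / bx
    v = (sy / bx) ** -2.0
    return float(np.sum(v * (ratios - theta_ivw) ** 2))


def cochran_q(h: HarmonizedSet) -> HetTest:
    """Cochran's Q heterogeneity test of the per-instrument ratio estimates."""
    if h.k < 2:
        raise InsufficientInstrumentsError(f"cochran_q requires k >= 2, got k = {h.k}")
    bx, _, by, sy = h.arrays()
    _check_bx(bx)
    w = sy ** -2.0
    theta = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    q = _q_statistic(bx, by, sy, theta)
    df = h.k - 1
    return HetTest(Q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger regression: weighted fit of β_Y on β_X with a free intercept.

    Exposure orientation is first fixed so every β_X ≥ 0 (both betas of a
    pair flip together), which the intercept interpretation requires.  The
    residual variance factor is floored at 1 (multiplicative random effects)
    and inference is two-sided t with k − 2 degrees of freedom.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError(
            f"egger requires k >= 3 (zero residual df at k = 2), got k = {h.k}")
    bx, _, by, sy = h.arrays()
    _check_bx(bx)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign

    w = sy ** -2.0
    # closed-form 2-parameter WLS: design [1, bx]
    sw = w.sum()
    swx = float(np.sum(w * bx))
    swx2 = float(np.sum(w * bx * bx))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swx2 - swx * swx
    if det <= 0:
        raise EstimationError("degenerate Egger design (all beta_exp equal?)")
    intercept = (swx2 * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det

    resid = by - intercept - slope * bx
    df = h.k - 2
    sigma2 = max(1.0, float(np.sum(w * resid * resid)) / df)
    var_slope = sigma2 * sw / det
    var_intercept = sigma2 * swx2 / det
    se_slope = float(np.sqrt(var_slope))
    se_intercept = float(np.sqrt(var_intercept))

    slope_est = _estimate("egger_slope", h.k, slope, se_slope, _t_p(slope, se_slope, df))
    return EggerResult(
        slope=slope_est,
        intercept=float(intercept),
        intercept_se=se_intercept,
        intercept_pvalue=_t_p(intercept, se_intercept, df),
    )


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate interpolates the sorted per-instrument ratios against
    their centred cumulative weights at probability one half; the SE is the
    standard deviation of the estimate over ``n_boot`` parametric resamples
    of both beta vectors.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError(f"weighted_median requires k >= 3, got k = {h.k}")
    bx, sx, by, sy = h.arrays()
    _check_bx(bx)
    beta = _weighted_median_point(bx, by, sy)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0.0] = np.finfo(float).tiny  # measure-zero guard
        boots[b] = _weighted_median_point(bxs, bys, sy)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", h.k, beta, se, _normal_p(beta, se))


def _weighted_median_point(bx, by, sy) -> float:
    ratios = by / bx
    v = (sy / bx) ** -2.0
    order = np.argsort(ratios)
    r = ratios[order]
    w = v[order] / v.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def max_likelihood(h: HarmonizedSet, max_iter: int = 500) -> MREstimate:
    """Maximum-likelihood causal estimate under independent normal errors.

    Model: β_Xj ~ N(ξ_j, σ_Xj²), β_Yj ~ N(θ·ξ_j, σ_Yj²), maximized jointly
    over θ and the nuisance true effects ξ.  Initialized at the fixed-effect
    IVW estimate and ξ = β_X; SE from the θ-component of the inverse observed
    information at the optimum.
    """
    if h.k < 2:
        raise InsufficientInstrumentsError(f"max_likelihood requires k >= 2, got k = {h.k}")
    bx, sx, by, sy = h.arrays()
    _check_bx(bx)
    vx, vy = sx ** 2.0, sy ** 2.0

    # The joint optimum factorizes: for fixed theta the nuisance true effects
    # have the closed-form optimum
    #   xi_j(theta) = (bx_j/vx_j + theta·by_j/vy_j) / (1/vx_j + theta²/vy_j),
    # and substituting it gives the exact profile negative log-likelihood
    #   f(theta) = ½ Σ (by_j − theta·bx_j)² / (vy_j + theta²·vx_j),
    # so the joint maximization reduces to a one-dimensional search.
    def profile_negll(theta: float) -> float:
        return float(0.5 * np.sum((by - theta * bx) ** 2 / (vy + theta * theta * vx)))

    w = sy ** -2.0
    theta0 = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    span = max(1.0, abs(theta0))
    try:
        res = optimize.minimize_scalar(
            profile_negll, bracket=(theta0 - span, theta0, theta0 + span),
            method="brent", options={"xtol": 1e-10, "maxiter": max_iter})
    except ValueError:
        # theta0 did not bracket the optimum; let scipy expand the bracket
        res = optimize.minimize_scalar(
            profile_negll, bracket=(theta0 - span, theta0 + span),
            method="brent", options={"xtol": 1e-10, "maxiter": max_iter})
    if not res.success:
        raise EstimationError(f"likelihood maximization failed: {res}")

    theta = float(res.x)
    xi = (bx / vx + theta * by / vy) / (1.0 / vx + theta * theta / vy)
    # observed information; Var(theta) via the Schur complement over the
    # diagonal xi block
    h_tt = float(np.sum(xi ** 2 / vy))
    h_tx = (2.0 * theta * xi - by) / vy
    h_xx = 1.0 / vx + theta ** 2 / vy
    denom = h_tt - float(np.sum(h_tx ** 2 / h_xx))
    if denom <= 0:
        raise EstimationError("observed information not positive definite at optimum")
    se = denom ** -0.5
    return _estimate("max_likelihood", h.k, float(theta), float(se), _normal_p(theta, se))
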