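"""Synthetic GWAS worlds with known causal structure.

The generator emulates the statistical shape of a two-sample MR study on a
quantitative metabolome: a modest reference panel for LD, an exposure cohort
(metabolite GWAS) and a larger, disjoint outcome cohort (blood-pressure
GWAS), each contributing per-SNP marginal regression estimates.

Genotypes are drawn under Hardy–Weinberg from per-SNP minor-allele
frequencies; LD comes from a latent AR(1) Gaussian per haplotype within each
block, thresholded at the allele-frequency quantile, so within-block
correlation decays geometrically with distance while blocks — separated by
more than any clumping window — are exactly independent.  Clumping truth is
therefore known: at most one instrument can survive per block.

Phenotypes follow the standard linear structural model.  In the exposure
sample, metabolite ``X = Σ_j α_j G_j + e`` with the causal SNPs explaining
``exposure_h2`` of unit variance.  In the outcome sample,
``Y = θ·X + Σ_j γ_j s_j G_j + ε`` where θ is the causal effect of interest
and γ are direct (pleiotropic) SNP effects, expressed per
exposure-increasing allele (``s_j = sign(α_j)``) so that a nonzero mean γ is
directional pleiotropy in the MR-Egger sense.  Summary statistics are the
marginal simple-regression estimates computed SNP by SNP in each sample —
LD induces correlated betas within blocks, which the clumping step of the
pipeline must neutralize.

Allele pairs are drawn from the non-complementary combinations only, so the
generated world contains no palindromic SNPs; strand ambiguity is exercised
by the harmonization unit tests instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ld import ReferencePanel
from .sumstats import COLUMNS, GwasSummary

# independent random streams per artifact, all derived from the user seed
_STREAM_META, _STREAM_PANEL, _STREAM_EXP, _STREAM_OUT, _STREAM_PHENO, _STREAM_ASSIGN = range(6)

# ordered (ref, alt) pairs that are not strand-palindromic
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


@dataclass
class SimConfig:
    """Parameters of the simulated world.

    Sample sizes default to desk-scale analogues of a metabolite GWAS cohort
    (n_exp = 8000), a blood-pressure GWAS (n_out = 20000) and a small LD
    reference panel (n_ref = 500).  ``pleiotropy_frac`` of the causal SNPs
    receive direct outcome effects drawn from N(pleiotropy_mean,
    pleiotropy_sd²) per exposure-increasing allele.
    """

    m_snps: int = 2000
    n_blocks: int = 100
    rho: float = 0.8           # within-block latent AR(1) correlation
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_ref: int = 500
    n_exp: int = 8000
    n_out: int = 20000
    k_causal: int = 20
    exposure_h2: float = 0.3
    theta: float = 0.0
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    # metabolome-scale scenario
    n_metabolites: int = 100
    n_causal_metabolites: int = 5
    theta_causal: float = 0.15
    frac_no_instruments: float = 0.3
    # genome layout
    block_gap_bp: int = 25_000_000   # > any clumping window, blocks independent
    snp_spacing_bp: int = 2_000

    def __post_init__(self) -> None:
        if self.n_blocks > self.m_snps:
            raise ValueError("need at least one SNP per block")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not (0.0 <= self.exposure_h2 < 1.0):
            raise ValueError("exposure_h2 must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must sit within (0, 0.5]")
        for nm in ("n_ref", "n_exp", "n_out"):
            if getattr(self, nm) < 2:
                raise ValueError(f"{nm} must be >= 2")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ValueError("pleiotropy_frac must be in [0, 1]")


# --- canonical scenario presets -------------------------------------------
# These freeze the "stated worlds" used by the statistical validation suite.

def calibration_config() -> SimConfig:
    """Null world (θ = 0, no pleiotropy) with 20 strong independent causal SNPs.

    Reduced to the causal SNPs only (one per block) so thousands of
    replicates stay cheap; per-SNP F ≈ h²/k · n_exp = 120.
    """
    return SimConfig(m_snps=20, n_blocks=20, rho=0.0, k_causal=20,
                     exposure_h2=0.3, theta=0.0)


def recovery_config(theta: float) -> SimConfig:
    """Strong-instrument world for parameter recovery (per-SNP F ≈ 400)."""
    return SimConfig(m_snps=10, n_blocks=10, rho=0.0, k_causal=10,
                     exposure_h2=0.5, theta=theta)


def balanced_pleiotropy_config(theta: float = 0.0) -> SimConfig:
    """Every causal SNP pleiotropic with mean-zero direct effects (InSIDE holds).

    Strong, dispersed instruments (h² = 0.5 over 20 SNPs) keep the
    instrument-strength I² near 1; θ defaults to 0 so the scenario isolates
    pleiotropy-induced intercept bias from the separate (known) attenuation
    of order θ·(1 − I²) that any nonzero causal effect leaks into the
    intercept at finite instrument strength.
    """
    return SimConfig(m_snps=20, n_blocks=20, rho=0.0, k_causal=20,
                     exposure_h2=0.5, theta=theta,
                     pleiotropy_frac=1.0, pleiotropy_mean=0.0, pleiotropy_sd=0.02)


def directional_pleiotropy_config(theta: float = 0.1) -> SimConfig:
    """Directional pleiotropy: all direct effects drawn around a positive mean.

    The mean direct effect is set around three intercept standard errors
    (≈ 0.02 at these sample sizes), i.e. clearly detectable pleiotropy.
    """
    return SimConfig(m_snps=20, n_blocks=20, rho=0.0, k_causal=20,
                     exposure_h2=0.5, theta=theta,
                     pleiotropy_frac=1.0, pleiotropy_mean=0.06, pleiotropy_sd=0.02)


def metabolome_config() -> SimConfig:
    """Desk-scale metabolome: 100 traits, 5 causal (|θ| = 0.12, 8 instruments
    each), ~30% of traits without genome-wide-significant SNPs.

    The planted effect keeps each causal SNP's outcome association well
    below genome-wide significance (per-SNP z ≈ 3.3, p ≈ 1e-3), because the
    selection pipeline *excludes* instruments directly associated with the
    outcome at 5e-8 — a stronger θ would strip a causal trait of its own
    instruments — while the pooled IVW signal (z ≈ 9–10) gives essentially
    full power against the metabolome-wide Bonferroni threshold.
    """
    return SimConfig(m_snps=2000, n_blocks=100, rho=0.8, k_causal=8,
                     exposure_h2=0.3, theta_causal=0.12,
                     n_metabolites=100, n_causal_metabolites=5,
                     frac_no_instruments=0.3)


@dataclass
class SimTruth:
    """Ground truth of one simulated world, keyed by trait id."""

    theta: dict[str, float]
    causal_snps: dict[str, list[str]]
    alpha: dict[str, dict[str, float]]
    gamma: dict[str, dict[str, float]]
    expected_instruments: dict[str, list[str]]
    no_instrument_traits: list[str] = field(default_factory=list)

    @property
    def expected_tested(self) -> list[str]:
        """Traits the pipeline is expected to test (≥ 1 surviving instrument)."""
        return [t for t, ivs in self.expected_instruments.items() if ivs]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.theta:
            rows.append((
                t, self.theta[t],
                ",".join(self.causal_snps.get(t, [])),
                ",".join(self.expected_instruments.get(t, [])),
                t in self.no_instrument_traits,
            ))
        return pd.DataFrame(rows, columns=[
            "trait_id", "theta", "causal_snps", "expected_instruments", "no_instrument"])


# ---------------------------------------------------------------------------
# genome layout and genotype sampling

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _block_sizes(cfg: SimConfig) -> np.ndarray:
    base, rem = divmod(cfg.m_snps, cfg.n_blocks)
    return np.array([base + (1 if b < rem else 0) for b in range(cfg.n_blocks)])


def variant_metadata(cfg: SimConfig, seed: int) -> pd.DataFrame:
    """Deterministic variant table: id, chrom, pos, ref/alt, maf, block.

    Depends only on (cfg, seed) so panels and summary statistics generated
    separately share one genome.
    """
    rng = _rng(seed, _STREAM_META)
    sizes = _block_sizes(cfg)
    rows = []
    per_chrom_count: dict[str, int] = {}
    snp_i = 0
    lo, hi = cfg.maf_range
    for b, size in enumerate(sizes):
        chrom = str((b % 22) + 1)
        idx_on_chrom = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = idx_on_chrom + 1
        start = 1 + idx_on_chrom * cfg.block_gap_bp
        # SNPs in tight LD share similar frequencies: one base MAF per block,
        # jittered per SNP (exactly equal frequencies would be an artifact,
        # grossly different ones would cap the attainable within-block r²)
        base_maf = rng.uniform(lo, hi)
        for j in range(size):
            ref, alt = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            maf = float(np.clip(base_maf + rng.normal(0.0, 0.01), lo, hi))
            rows.append((f"rs{snp_i + 1:06d}", chrom, start + j * cfg.snp_spacing_bp,
                         ref, alt, maf, b))
            snp_i += 1
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "maf", "block"])


def _sample_dosages(meta: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator,
                    n_ind: int) -> np.ndarray:
    """(m, n_ind) float32 alt-allele dosages with within-block AR(1) LD."""
    m = len(meta)
    thr = stats.norm.ppf(meta["maf"].to_numpy()).astype(np.float32)
    G = np.empty((m, n_ind), dtype=np.float32)
    n_hap = 2 * n_ind
    rho = cfg.rho
    for b, idx in meta.groupby("block", sort=True).indices.items():
        size = len(idx)
        E = rng.standard_normal((size, n_hap), dtype=np.float32)
        if rho > 0.0 and size > 1:
            # lower-triangular AR(1) mixing: corr(z_j, z_k) = rho^|j-k|
            L = np.zeros((size, size), dtype=np.float32)
            powers = rho ** np.arange(size)
            for j in range(size):
                L[j, 0] = powers[j]
                if j:
                    L[j, 1:j + 1] = powers[j - 1::-1][:j] * np.float32(np.sqrt(1 - rho * rho))
            Z = L @ E
        else:
            Z = E
        H = (Z < thr[idx, None]).astype(np.float32)
        G[idx] = H[:, :n_ind] + H[:, n_ind:]
    return G


def simulate_panel(cfg: SimConfig, seed: int) -> ReferencePanel:
    """A reference panel of ``n_ref`` individuals on the cfg/seed genome."""
    meta = variant_metadata(cfg, seed)
    G = _sample_dosages(meta, cfg, _rng(seed, _STREAM_PANEL), cfg.n_ref)
    variants = meta[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    return ReferencePanel(variants, G.astype(float))


# ---------------------------------------------------------------------------
# marginal summary statistics

def _marginal_stats(G: np.ndarray, Y: np.ndarray):
    """Per-SNP simple-regression estimates of each column of Y on each row of G.

    Returns (beta, se, pval, eaf) with shape (m,) when Y is 1-D and (m, t)
    when Y is (n, t).
    """
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n = G.shape[1]
    s1 = G.sum(axis=1, dtype=np.float64)
    s2 = np.einsum("ij,ij->i", G, G, dtype=np.float64)
    gm = s1 / n
    sgg = s2 - n * gm * gm                       # Σ (g - ḡ)²
    ym = Y.mean(axis=0)
    yc = (Y - ym).astype(np.float32)
    sgy = (G @ yc).astype(np.float64)            # Σ (g - ḡ)(y - ȳ) given Σ yc = 0
    syy = np.einsum("ij,ij->j", yc, yc, dtype=np.float64)

    ok = sgg > 0
    sgg_safe = np.where(ok, sgg, 1.0)
    beta = sgy / sgg_safe[:, None]
    rss = np.maximum(syy[None, :] - beta * sgy, 1e-300)
    se = np.sqrt(rss / (n - 2) / sgg_safe[:, None])
    beta[~ok] = 0.0
    se[~ok] = 1.0
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    np.clip(pval, np.nextafter(0.0, 1.0), 1.0, out=pval)
    eaf = gm / 2.0
    if squeeze:
        return beta[:, 0], se[:, 0], pval[:, 0], eaf
    return beta, se, pval, eaf


def _make_summary(trait_id: str, trait_type: str, meta: pd.DataFrame,
                  beta, se, pval, eaf, n: int) -> GwasSummary:
    table = pd.DataFrame({
        "variant_id": meta["variant_id"].to_numpy(),
        "chrom": meta["chrom"].to_numpy(),
        "pos": meta["pos"].to_numpy(),
        "ea": meta["alt"].to_numpy(),
        "oa": meta["ref"].to_numpy(),
        "eaf": np.asarray(eaf, dtype=float),
        "beta": np.asarray(beta, dtype=float),
        "se": np.asarray(se, dtype=float),
        "pval": np.asarray(pval, dtype=float),
        "n": float(n),
    }, columns=COLUMNS)
    return GwasSummary(trait_id, trait_type, table)


# ---------------------------------------------------------------------------
# causal architecture helpers

def _draw_effects(rng: np.random.Generator, k: int, var_g: np.ndarray, h2: float) -> np.ndarray:
    """Per-allele effects scaled to explain h2 jointly.

    Effects are drawn on the standardized-genotype scale (α ∝ 1/√var_g), so
    each causal SNP's expected share of h2 is u²/Σu² with a dispersed factor
    u ~ U(0.6, 1.4): dispersion of instrument strength is what identifies
    the MR-Egger intercept, while the lower bound keeps every causal SNP
    individually strong (per-SNP F stays well above the weak-instrument
    cutoff at the default sample sizes).
    """
    u = rng.uniform(0.6, 1.4, size=k)
    s = rng.choice([-1.0, 1.0], size=k)
    scale = np.sqrt(h2 / np.sum(u * u)) if h2 > 0 else 0.0
    return s * u * scale / np.sqrt(var_g)


def _pick_causal_snps(meta: pd.DataFrame, rng: np.random.Generator, blocks) -> np.ndarray:
    """One random SNP index per block — instruments survive clumping separately."""
    out = []
    grouped = meta.groupby("block", sort=True).indices
    for b in blocks:
        idx = grouped[b]
        out.append(int(idx[rng.integers(len(idx))]))
    return np.array(out)


def expected_instrument_sets(
    exposures: list[GwasSummary],
    outcome: GwasSummary,
    meta: pd.DataFrame,
    p_threshold: float = 5e-8,
    p_exclusion: float = 5e-8,
) -> dict[str, list[str]]:
    """Truth-side prediction of each trait's surviving instrument set.

    Uses the generator's knowledge that LD blocks are mutually independent
    and separated beyond the clumping window: per block, the best-p
    genome-wide-significant SNP is the clump representative, and it survives
    iff its outcome p-value exceeds the exclusion threshold.  (Every GWS SNP
    here has F ≫ 10 automatically: p < 5e-8 implies (beta/se)² > 29.7.)
    """
    block_of = meta.set_index("variant_id")["block"]
    out_p = outcome.table.set_index("variant_id")["pval"]
    result: dict[str, list[str]] = {}
    for gw in exposures:
        t = gw.table
        sig = t[t["pval"] < p_threshold]
        if sig.empty:
            result[gw.trait_id] = []
            continue
        sig = sig.assign(block=block_of.loc[sig["variant_id"]].to_numpy())
        sig = sig.sort_values(["pval", "variant_id"], kind="mergesort")
        reps = sig.groupby("block", sort=True).head(1)
        kept = [v for v in reps["variant_id"] if float(out_p.loc[v]) > p_exclusion]
        result[gw.trait_id] = sorted(kept)
    return result


# ---------------------------------------------------------------------------
# scenarios

def simulate_two_sample(cfg: SimConfig, seed: int):
    """One exposure, one outcome, disjoint samples.

    Returns ``(exposure, outcome, truth)``; trait ids are ``"X"`` and
    ``"Y"``.  Residual outcome variance is set so Var(Y) ≈ 1 (floored at
    0.05 when the genetic part already explains nearly everything).
    """
    meta = variant_metadata(cfg, seed)
    rng_assign = _rng(seed, _STREAM_ASSIGN)
    rng_pheno = _rng(seed, _STREAM_PHENO)

    blocks = rng_assign.permutation(cfg.n_blocks)[: cfg.k_causal]
    cidx = _pick_causal_snps(meta, rng_assign, sorted(blocks))
    maf = meta["maf"].to_numpy()[cidx]
    var_g = 2.0 * maf * (1.0 - maf)
    alpha = _draw_effects(rng_assign, cfg.k_causal, var_g, cfg.exposure_h2)

    n_pleio = int(round(cfg.pleiotropy_frac * cfg.k_causal))
    pleio_pos = rng_assign.choice(cfg.k_causal, size=n_pleio, replace=False)
    gamma = np.zeros(cfg.k_causal)
    if n_pleio:
        gamma[pleio_pos] = rng_assign.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n_pleio)

    # exposure sample
    G_exp = _sample_dosages(meta, cfg, _rng(seed, _STREAM_EXP), cfg.n_exp)
    gv_exp = alpha @ G_exp[cidx].astype(np.float64)
    x = gv_exp + rng_pheno.normal(0.0, np.sqrt(1.0 - cfg.exposure_h2), cfg.n_exp)
    b, s, p, eaf = _marginal_stats(G_exp, x)
    exposure = _make_summary("X", "exposure", meta, b, s, p, eaf, cfg.n_exp)
    del G_exp

    # outcome sample: Y = θ·X + direct effects (per exposure-increasing allele) + ε
    G_out = _sample_dosages(meta, cfg, _rng(seed, _STREAM_OUT), cfg.n_out)
    gv_out = alpha @ G_out[cidx].astype(np.float64)
    x_out = gv_out + rng_pheno.normal(0.0, np.sqrt(1.0 - cfg.exposure_h2), cfg.n_out)
    direct = (np.sign(alpha) * gamma) @ G_out[cidx].astype(np.float64)
    var_direct = float(np.sum(gamma * gamma * var_g)
                       + 2.0 * cfg.theta * np.sum(np.abs(alpha) * gamma * var_g))
    resid = max(0.05, 1.0 - cfg.theta ** 2 - var_direct)
    y = cfg.theta * x_out + direct + rng_pheno.normal(0.0, np.sqrt(resid), cfg.n_out)
    b, s, p, eaf = _marginal_stats(G_out, y)
    outcome = _make_summary("Y", "outcome", meta, b, s, p, eaf, cfg.n_out)
    del G_out

    ids = meta["variant_id"].to_numpy()[cidx]
    truth = SimTruth(
        theta={"X": cfg.theta},
        causal_snps={"X": sorted(ids)},
        alpha={"X": dict(zip(ids, alpha))},
        gamma={"X": dict(zip(ids, np.sign(alpha) * gamma))},
        expected_instruments=expected_instrument_sets([exposure], outcome, meta),
    )
    return exposure, outcome, truth


def simulate_metabolome(cfg: SimConfig, seed: int):
    """Many exposures sharing one outcome sample.

    A random subset of ``n_causal_metabolites`` traits receives a causal
    effect ±``theta_causal`` (random sign); a fraction
    ``frac_no_instruments`` of the remaining traits gets no causal SNPs and
    hence (almost surely) no genome-wide-significant hits.  Causal traits
    draw their SNP blocks from a reserved pool so their instruments are
    uncorrelated with every null trait's instruments.
    """
    if cfg.n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    if cfg.n_causal_metabolites > cfg.n_metabolites:
        raise ValueError("n_causal_metabolites cannot exceed n_metabolites")
    need = cfg.n_causal_metabolites * cfg.k_causal
    if need > cfg.n_blocks:
        raise ValueError(
            f"{cfg.n_causal_metabolites} causal traits x {cfg.k_causal} instruments "
            f"need {need} exclusive blocks but only {cfg.n_blocks} exist")

    meta = variant_metadata(cfg, seed)
    rng_assign = _rng(seed, _STREAM_ASSIGN)
    rng_pheno = _rng(seed, _STREAM_PHENO)
    maf_all = meta["maf"].to_numpy()

    ids = [f"M{i + 1:04d}" for i in range(cfg.n_metabolites)]
    causal_mets = sorted(rng_assign.choice(ids, cfg.n_causal_metabolites, replace=False))
    rest = [m for m in ids if m not in causal_mets]
    no_instr = [m for m in rest if rng_assign.random() < cfg.frac_no_instruments]
    no_instr_set = set(no_instr)

    thetas = {m: 0.0 for m in ids}
    for m in causal_mets:
        thetas[m] = float(cfg.theta_causal * rng_assign.choice([-1.0, 1.0]))

    perm = rng_assign.permutation(cfg.n_blocks)
    reserved = {m: perm[i * cfg.k_causal:(i + 1) * cfg.k_causal]
                for i, m in enumerate(causal_mets)}
    shared_pool = perm[need:]

    causal_idx: dict[str, np.ndarray] = {}
    alphas: dict[str, np.ndarray] = {}
    for m in ids:
        if m in no_instr_set:
            causal_idx[m] = np.array([], dtype=int)
            alphas[m] = np.array([])
            continue
        if m in reserved:
            blocks = reserved[m]
        else:
            blocks = rng_assign.choice(shared_pool, cfg.k_causal, replace=False)
        cidx = _pick_causal_snps(meta, rng_assign, sorted(int(b) for b in blocks))
        maf = maf_all[cidx]
        causal_idx[m] = cidx
        alphas[m] = _draw_effects(rng_assign, cfg.k_causal, 2 * maf * (1 - maf), cfg.exposure_h2)

    # exposure sample: all metabolite phenotypes measured on one cohort
    G_exp = _sample_dosages(meta, cfg, _rng(seed, _STREAM_EXP), cfg.n_exp)
    X = np.empty((cfg.n_exp, cfg.n_metabolites))
    for j, m in enumerate(ids):
        noise_sd = np.sqrt(1.0 - (cfg.exposure_h2 if len(causal_idx[m]) else 0.0))
        gv = (alphas[m] @ G_exp[causal_idx[m]].astype(np.float64)
              if len(causal_idx[m]) else 0.0)
        X[:, j] = gv + rng_pheno.normal(0.0, noise_sd, cfg.n_exp)
    b, s, p, eaf = _marginal_stats(G_exp, X)
    exposures = [
        _make_summary(m, "exposure", meta, b[:, j], s[:, j], p[:, j], eaf, cfg.n_exp)
        for j, m in enumerate(ids)
    ]
    del G_exp

    # shared outcome sample
    G_out = _sample_dosages(meta, cfg, _rng(seed, _STREAM_OUT), cfg.n_out)
    y = np.zeros(cfg.n_out)
    for m in causal_mets:
        gv = alphas[m] @ G_out[causal_idx[m]].astype(np.float64)
        x_out = gv + rng_pheno.normal(0.0, np.sqrt(1.0 - cfg.exposure_h2), cfg.n_out)
        y += thetas[m] * x_out
    resid = max(0.05, 1.0 - sum(thetas[m] ** 2 for m in causal_mets))
    y += rng_pheno.normal(0.0, np.sqrt(resid), cfg.n_out)
    b, s, p, eaf = _marginal_stats(G_out, y)
    outcome = _make_summary("BP", "outcome", meta, b, s, p, eaf, cfg.n_out)
    del G_out

    vid = meta["variant_id"].to_numpy()
    truth = SimTruth(
        theta=thetas,
        causal_snps={m: sorted(vid[causal_idx[m]]) for m in ids},
        alpha={m: dict(zip(vid[causal_idx[m]], alphas[m])) for m in ids},
        gamma={m: {} for m in ids},
        expected_instruments=expected_instrument_sets(exposures, outcome, meta),
        no_instrument_traits=no_instr,
    )
    return exposures, outcome, truth


def scaled(cfg: SimConfig, **overrides) -> SimConfig:
    """A copy of ``cfg`` with fields replaced (convenience for tests/CLI)."""
    return replace(cfg, **overrides)
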