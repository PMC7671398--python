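"""Generative model for two-sample MR simulation studies.

Individual-level data for an exposure sample, an outcome sample and a
reference panel are generated under the structural model

    x = G1 @ gamma + U_x @ eta_x + e1
    y = beta0 * x2 + G2 @ alpha + U_y @ eta_y + e2

where ``gamma`` are SNP effects on the exposure, ``alpha`` direct
(horizontally pleiotropic) SNP effects on the outcome, and the confounder
coefficient pairs (eta_x, eta_y) are correlated so that shared confounding
biases a naive regression of outcome on exposure. The outcome sample does
not observe the exposure-sample x, so a latent exposure ``x2`` is generated
for sample 2 from the same structural equation (same gamma, same confounder
matrix U_y as y), preserving the within-sample confounding path.

Genotypes are dosages in {0,1,2}: a latent Gaussian with block-autoregressive
correlation Sigma(rho)_ij = rho^|i-j| is cut at the Hardy-Weinberg thresholds
for each SNP's minor allele frequency. Signal magnitudes are controlled by
heritabilities h2_gamma = var(beta0*G*gamma)/var(y) and
h2_alpha = var(G*alpha)/var(y); scaling is empirical (effects are rescaled
against realized variances on the generated sample), so the configured
ratios hold per replicate rather than only in expectation.

Summary statistics are produced by per-SNP univariate regression after
mean-centering both the dosages and the trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import ldmat as _ldmat
from .sumstats_io import HarmonizedDataset

__all__ = [
    "SimulationConfig",
    "TrueEffects",
    "SimulatedStudy",
    "draw_block_genotypes",
    "simulate_effects",
    "simulate_two_sample",
    "single_variant_summary",
    "make_dataset",
]

# Non-genetic variance budget on each trait: confounders contribute 0.3 and
# the trait total is normalized to genetic + 0.9 (for the outcome, to 1.0),
# i.e. a 30% confounder share when the genetic share is h2 and var = 1.
_CONF_VAR = 0.3
_NONGENETIC_VAR = 0.9


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative design of a two-sample MR simulation.

    Defaults are the base simulation conditions: samples of 20 000 with a
    500-SNP genome in 10 blocks of 50, moderate LD (rho = 0.4), MAF uniform
    on (0.05, 0.5), exposure-mediated heritability 0.1, dense pleiotropy at
    heritability 0.05, causal effect 0.1, 50 shared confounders whose
    exposure/outcome coefficients correlate at 0.8.
    """

    n1: int = 20_000
    n2: int = 20_000
    n3: int = 500
    M: int = 10
    block_size: int = 50
    rho: float = 0.4
    maf_low: float = 0.05
    maf_high: float = 0.5
    h2_gamma: float = 0.1
    h2_alpha: float = 0.05
    pleiotropy_sparsity: float = 1.0
    beta0: float = 0.1
    q: int = 50
    eta_corr: float = 0.8
    seed: int = 0

    @property
    def p(self) -> int:
        return self.M * self.block_size

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3", "M", "block_size", "q"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.h2_gamma < 0 or self.h2_alpha < 0 or self.h2_gamma + self.h2_alpha >= 1:
            raise ValueError("need h2_gamma, h2_alpha >= 0 with h2_gamma + h2_alpha < 1")
        if not 0.0 < self.pleiotropy_sparsity <= 1.0:
            raise ValueError("pleiotropy_sparsity must be in (0, 1]")
        if self.h2_gamma == 0 and self.beta0 != 0:
            raise ValueError("inconsistent config: beta0 != 0 requires h2_gamma > 0")


@dataclass
class TrueEffects:
    """Realized effect vectors and noise scales of one simulated study."""

    gamma: np.ndarray
    alpha: np.ndarray
    eta_x: np.ndarray
    eta_y: np.ndarray
    sigma2_e1: float
    sigma2_e2: float


@dataclass
class SimulatedStudy:
    """Individual-level draws: genotypes, traits, truth and MAFs."""

    G1: np.ndarray
    G2: np.ndarray
    G3: np.ndarray
    x: np.ndarray
    y: np.ndarray
    truth: TrueEffects
    maf: np.ndarray


def draw_maf(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(config.maf_low, config.maf_high, size=config.p)


def draw_block_genotypes(
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    maf: np.ndarray | None = None,
) -> np.ndarray:
    """Draw an ``n x p`` dosage matrix with block-AR latent correlation.

    Within each block the latent Gaussian has AR(1) correlation
    rho^|i-j|; each SNP's latent value is cut at Phi^-1((1-f)^2) and
    Phi^-1((1-f)^2 + 2f(1-f)) so dosages 0/1/2 occur with the
    Hardy-Weinberg frequencies for minor allele frequency ``f``.
    """
    if maf is None:
        maf = draw_maf(config, rng)
    p, bs, rho = config.p, config.block_size, config.rho
    eps = rng.standard_normal((n, p))
    Z = np.empty((n, p))
    scale = np.sqrt(1.0 - rho * rho)
    for b in range(config.M):
        s = b * bs
        Z[:, s] = eps[:, s]
        for j in range(s + 1, s + bs):
            Z[:, j] = rho * Z[:, j - 1] + scale * eps[:, j]
    t1 = stats.norm.ppf((1.0 - maf) ** 2)
    t2 = stats.norm.ppf((1.0 - maf) ** 2 + 2.0 * maf * (1.0 - maf))
    G = (Z >= t1).astype(np.int8) + (Z >= t2).astype(np.int8)
    return G


def _solve_noise_scale(fixed: np.ndarray, z: np.ndarray, target_var: float) -> float:
    """Scale for raw noise ``z`` so that var(fixed + s*z) equals target_var.

    Solves the realized-variance quadratic a*s^2 + b*s + c = 0 exactly on
    the generated sample, absorbing the empirical cross-covariance between
    the structural part and the noise draw.
    """
    a = float(np.var(z))
    b = 2.0 * float(np.cov(fixed, z, bias=True)[0, 1])
    c = float(np.var(fixed)) - target_var
    if c >= 0:
        raise ValueError(
            "variance budget infeasible: structural variance "
            f"{c + target_var:.4f} already exceeds target {target_var:.4f}"
        )
    disc = b * b - 4.0 * a * c
    return (-b + np.sqrt(disc)) / (2.0 * a)


def _scale_to_var(component: np.ndarray, target_var: float) -> float:
    v = float(np.var(component))
    if v == 0.0:
        raise ValueError("cannot scale a zero-variance component")
    return np.sqrt(target_var / v)


def simulate_effects(
    config: SimulationConfig,
    rng: np.random.Generator,
    G1: np.ndarray | None = None,
    G2: np.ndarray | None = None,
) -> TrueEffects:
    """Draw and empirically rescale the true effect vectors.

    Gamma entries are i.i.d. Gaussian; alpha is Gaussian on a uniformly
    random support of ``round(sparsity * p)`` SNPs (all of them when dense).
    Scaling targets the realized variances on the generated genotype
    samples, so the configured heritabilities hold per replicate. When
    genotypes are not supplied they are drawn internally (fresh MAFs).
    """
    if G1 is None or G2 is None:
        maf = draw_maf(config, rng)
        if G1 is None:
            G1 = draw_block_genotypes(config.n1, config, rng, maf)
        if G2 is None:
            G2 = draw_block_genotypes(config.n2, config, rng, maf)
    eff, *_ = _scaled_effects(config, rng, G1, G2)
    return eff


def _scaled_effects(config, rng, G1, G2):
    """Core scaling logic; returns (TrueEffects, x, x2, y)."""
    p, q, beta0 = config.p, config.q, config.beta0
    G1c = G1 - G1.mean(axis=0)
    G2c = G2 - G2.mean(axis=0)

    # raw draws ------------------------------------------------------------
    gamma = rng.standard_normal(p) if config.h2_gamma > 0 else np.zeros(p)
    alpha = np.zeros(p)
    if config.h2_alpha > 0:
        k = int(round(config.pleiotropy_sparsity * p))
        support = rng.choice(p, size=k, replace=False)
        alpha[support] = rng.standard_normal(k)
    cov_eta = np.array([[1.0, config.eta_corr], [config.eta_corr, 1.0]])
    eta = rng.multivariate_normal(np.zeros(2), cov_eta, size=q)
    eta_x, eta_y = eta[:, 0].copy(), eta[:, 1].copy()
    U_x = rng.standard_normal((config.n1, q))
    U_y = rng.standard_normal((config.n2, q))
    e1_raw = rng.standard_normal(config.n1)
    e1p_raw = rng.standard_normal(config.n2)
    e2_raw = rng.standard_normal(config.n2)

    # exposure effects: under a nonzero causal effect, gamma is pinned by the
    # outcome-side target var(beta0 * G2 gamma) = h2_gamma (var(y) = 1);
    # under the null it is pinned by the exposure side var(G1 gamma) = h2_gamma.
    if config.h2_gamma > 0:
        if beta0 != 0.0:
            gamma *= _scale_to_var(beta0 * (G2c @ gamma), config.h2_gamma)
        else:
            gamma *= _scale_to_var(G1c @ gamma, config.h2_gamma)

    # exposure sample ------------------------------------------------------
    g1 = G1c @ gamma
    eta_x *= _scale_to_var(U_x @ eta_x, _CONF_VAR)
    fixed_x = g1 + U_x @ eta_x
    var_x_target = float(np.var(g1)) + _NONGENETIC_VAR
    s_e1 = _solve_noise_scale(fixed_x, e1_raw, var_x_target)
    x = fixed_x + s_e1 * e1_raw

    # outcome sample -------------------------------------------------------
    if config.h2_alpha > 0:
        alpha *= _scale_to_var(G2c @ alpha, config.h2_alpha)
    eta_y *= _scale_to_var(U_y @ eta_y, _CONF_VAR)
    x2 = G2c @ gamma + U_y @ eta_x + s_e1 * e1p_raw
    fixed_y = beta0 * x2 + G2c @ alpha + U_y @ eta_y
    s_e2 = _solve_noise_scale(fixed_y, e2_raw, 1.0)
    y = fixed_y + s_e2 * e2_raw

    eff = TrueEffects(
        gamma=gamma,
        alpha=alpha,
        eta_x=eta_x,
        eta_y=eta_y,
        sigma2_e1=float(s_e1**2),
        sigma2_e2=float(s_e2**2),
    )
    return eff, x, x2, y


def simulate_two_sample(config: SimulationConfig) -> SimulatedStudy:
    """Generate exposure/outcome samples plus a reference panel.

    All three genotype matrices share one MAF vector and the same block-AR
    latent correlation (a single population). Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    maf = draw_maf(config, rng)
    G1 = draw_block_genotypes(config.n1, config, rng, maf)
    G2 = draw_block_genotypes(config.n2, config, rng, maf)
    G3 = draw_block_genotypes(config.n3, config, rng, maf)
    truth, x, _x2, y = _scaled_effects(config, rng, G1, G2)
    return SimulatedStudy(G1=G1, G2=G2, G3=G3, x=x, y=y, truth=truth, maf=maf)


def single_variant_summary(G: np.ndarray, trait: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP univariate regression estimates and squared standard errors.

    Both trait and dosages are mean-centered; thereafter, for each SNP k,

        estimate_k = (g_k' g_k)^-1 g_k' y
        se2_k      = (n g_k' g_k)^-1 (y - g_k estimate_k)'(y - g_k estimate_k)

    with divisor exactly n. Constant dosage columns are excluded (NaN
    output) with a warning.
    """
    G = np.asarray(G, dtype=float)
    trait = np.asarray(trait, dtype=float)
    n, p = G.shape
    if trait.shape != (n,):
        raise ValueError("trait length does not match genotype rows")
    if n < 3:
        raise ValueError("need at least 3 samples")
    Gc = G - G.mean(axis=0)
    t = trait - trait.mean()
    gg = np.einsum("ij,ij->j", Gc, Gc)
    const = gg == 0.0
    if np.any(const):
        warnings.warn(f"excluding {int(const.sum())} constant SNP column(s)")
    gg_safe = np.where(const, 1.0, gg)
    gty = Gc.T @ t
    est = gty / gg_safe
    tt = float(t @ t)
    ss = tt - est * gty  # residual sum of squares per SNP
    se2 = ss / (n * gg_safe)
    est[const] = np.nan
    se2[const] = np.nan
    return est, se2


def make_dataset(
    config: SimulationConfig,
    lam: float = 0.055,
    tau: float = 1e-3,
) -> tuple[HarmonizedDataset, _ldmat.BlockLDMatrix, TrueEffects]:
    """Simulate, reduce to summary statistics and estimate the LD matrix.

    Composes the full pipeline the model consumes: two-sample simulation,
    per-SNP regression in each sample, and the shrunk block LD matrix
    estimated from the reference panel G3 with shrinkage ``lam``
    (0.055 by default, the value used for simulation workflows).
    Block assignment matches the generating blocks.
    """
    study = simulate_two_sample(config)
    gamma_hat, s2_gamma = single_variant_summary(study.G1, study.x)
    Gamma_hat, s2_Gamma = single_variant_summary(study.G2, study.y)
    assignment = np.repeat(np.arange(config.M), config.block_size)
    R_emp = _ldmat.empirical_block_corr(study.G3, assignment)
    R = _ldmat.shrink_block_corr(R_emp, lam=lam, tau=tau)
    p = config.p
    meta = pd.DataFrame(
        {
            "snp": [f"snp{k + 1}" for k in range(p)],
            "chrom": np.ones(p, dtype=int),
            "pos": np.arange(1, p + 1) * 1000,
            "a1": ["A"] * p,
            "a2": ["G"] * p,
        }
    )
    data = HarmonizedDataset(
        snp=meta,
        gamma_hat=gamma_hat,
        s_gamma=np.sqrt(s2_gamma),
        Gamma_hat=Gamma_hat,
        s_Gamma=np.sqrt(s2_Gamma),
        block_assignment=assignment,
    )
    return data, R, study.truth
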