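"""Reference two-sample MR estimators: IVW, MR-Egger and greedy LD pruning.

Both estimators assume independent instruments, so correlated SNPs are
removed first by greedy pruning against the reference LD matrix, mirroring
clumping practice: visit SNPs by ascending priority p-value and keep a SNP
only if its squared correlation with everything already kept stays below the
threshold.

IVW is the no-intercept weighted regression of outcome effects on exposure
effects through the origin with weights 1/s_Gamma^2; MR-Egger frees the
intercept, which absorbs directional pleiotropy but makes the estimate
depend on the allele orientation of each SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ldmat import BlockLDMatrix
from .sumstats_io import HarmonizedDataset

__all__ = ["BaselineResult", "greedy_prune", "ivw", "egger"]


@dataclass
class BaselineResult:
    method: str
    beta: float
    se: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None


def greedy_prune(
    data: HarmonizedDataset,
    R: BlockLDMatrix,
    r2_threshold: float = 0.001,
    priority: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy LD pruning; returns retained SNP indices in original order.

    ``priority`` supplies per-SNP p-values (normally from an independent
    screening study) visited in ascending order; when omitted, Wald p-values
    from the exposure effects are used instead (documented fallback — this
    reuses the exposure study for ranking). Cross-block correlation is zero
    by construction; within a block r^2 is computed from R with its diagonal
    normalized out, so shrunk matrices are handled correctly.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    p = data.p
    if priority is None:
        z = data.gamma_hat / data.s_gamma
        priority = 2.0 * stats.norm.sf(np.abs(z))
    priority = np.asarray(priority, dtype=float)
    if priority.shape != (p,):
        raise ValueError("priority length must equal the SNP count")

    # per-SNP block range and correlation rows
    starts = np.empty(p, dtype=int)
    corr = {}
    for (start, stop), mat in R.blocks:
        d = np.sqrt(np.diag(mat))
        corr[(start, stop)] = mat / np.outer(d, d)
        starts[start:stop] = start

    retained: list[int] = []
    retained_mask = np.zeros(p, dtype=bool)
    for k in np.argsort(priority, kind="stable"):
        start = starts[k]
        rng_key = next(key for key in corr if key[0] == start)
        block = corr[rng_key]
        stop = rng_key[1]
        ok = True
        for j in retained:
            if start <= j < stop and block[k - start, j - start] ** 2 >= r2_threshold:
                ok = False
                break
        if ok:
            retained.append(int(k))
            retained_mask[k] = True
    return np.nonzero(retained_mask)[0]


def ivw(data: HarmonizedDataset, idx: np.ndarray | None = None) -> BaselineResult:
    """Inverse-variance weighted estimate on (pruned) independent SNPs.

        beta = sum w_k gamma_k Gamma_k / sum w_k gamma_k^2,  w_k = s_Gamma_k^-2
        se   = (sum w_k gamma_k^2)^(-1/2)
    """
    if idx is None:
        idx = np.arange(data.p)
    g = data.gamma_hat[idx]
    G = data.Gamma_hat[idx]
    w = data.s_Gamma[idx] ** -2
    denom = float(np.sum(w * g * g))
    if denom == 0.0:
        raise ValueError("all exposure effects are zero")
    beta = float(np.sum(w * g * G)) / denom
    return BaselineResult(method="ivw", beta=beta, se=denom**-0.5, n_snps=len(idx))


def egger(
    data: HarmonizedDataset,
    idx: np.ndarray | None = None,
    multiplicative_random_effects: bool = False,
) -> BaselineResult:
    """MR-Egger: weighted regression of Gamma_hat on gamma_hat with intercept.

    Weighted least squares with weights 1/s_Gamma^2; standard errors scale
    (X'WX)^-1 by the maximum-likelihood residual variance RSS_w / n.
    With ``multiplicative_random_effects`` the scale becomes
    max(1, RSS_w / (n - 2)), the usual over-dispersion inflation.
    """
    if idx is None:
        idx = np.arange(data.p)
    if len(idx) < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    g = data.gamma_hat[idx]
    G = data.Gamma_hat[idx]
    w = data.s_Gamma[idx] ** -2
    n = len(idx)
    X = np.column_stack([np.ones(n), g])
    XtW = X.T * w
    A = XtW @ X
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("exposure effects are constant/collinear")
    coef = np.linalg.solve(A, XtW @ G)
    resid = G - X @ coef
    rss_w = float(np.sum(w * resid**2))
    if multiplicative_random_effects:
        scale = max(1.0, rss_w / (n - 2))
    else:
        scale = rss_w / n
    cov = scale * np.linalg.inv(A)
    return BaselineResult(
        method="egger",
        beta=float(coef[1]),
        se=float(np.sqrt(cov[1, 1])),
        n_snps=n,
        intercept=float(coef[0]),
        intercept_se=float(np.sqrt(cov[0, 0])),
    )
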