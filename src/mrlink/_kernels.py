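"""Numba-jitted coordinate-ascent sweep for the variational E-step.

One sweep updates q(gamma_k) for k = 1..p_b then q(alpha_k) for k = 1..p_b
within a single LD block, Gauss-Seidel style (each coordinate update sees
the freshest means of the others). The running products Omega @ mu are
maintained incrementally, so a sweep costs O(p_b^2).
"""

import numpy as np
from numba import njit


@njit(cache=False)
def sweep_block(mu_g, v_g, mu_a, v_a, Og, OG, bg, bG,
                xi, beta0, inv_sg2, inv_sa2, use_alpha):
    pb = mu_g.shape[0]
    tg = Og @ mu_g
    w = OG @ mu_g
    u = OG @ mu_a
    for k in range(pb):
        old = mu_g[k]
        vk = 1.0 / (xi * xi * Og[k, k] + beta0 * beta0 * OG[k, k] + inv_sg2)
        num = xi * (bg[k] - xi * (tg[k] - Og[k, k] * old)) \
            + beta0 * (bG[k] - beta0 * (w[k] - OG[k, k] * old) - u[k])
        new = vk * num
        v_g[k] = vk
        mu_g[k] = new
        d = new - old
        if d != 0.0:
            for j in range(pb):
                tg[j] += Og[j, k] * d
                w[j] += OG[j, k] * d
    if use_alpha:
        for k in range(pb):
            old = mu_a[k]
            vk = 1.0 / (OG[k, k] + inv_sa2)
            num = bG[k] - (u[k] - OG[k, k] * old) - beta0 * w[k]
            new = vk * num
            v_a[k] = vk
            mu_a[k] = new
            d = new - old
            if d != 0.0:
                for j in range(pb):
                    u[j] += OG[j, k] * d
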