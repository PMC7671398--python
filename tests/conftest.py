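import numpy as np
import pandas as pd
import pytest

from mrlink import BlockLDMatrix, HarmonizedDataset


def toy_dataset(
    gamma_hat,
    Gamma_hat,
    s_gamma,
    s_Gamma,
    block_sizes=None,
):
    """Build a HarmonizedDataset from raw arrays (single chromosome)."""
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    p = len(gamma_hat)
    s_gamma = np.broadcast_to(np.asarray(s_gamma, dtype=float), (p,)).copy()
    s_Gamma = np.broadcast_to(np.asarray(s_Gamma, dtype=float), (p,)).copy()
    if block_sizes is None:
        block_sizes = [p]
    assignment = np.repeat(np.arange(len(block_sizes)), block_sizes)
    meta = pd.DataFrame(
        {
            "snp": [f"snp{k}" for k in range(p)],
            "chrom": 1,
            "pos": np.arange(1, p + 1),
            "a1": "A",
            "a2": "G",
        }
    )
    return HarmonizedDataset(
        snp=meta,
        gamma_hat=gamma_hat,
        Gamma_hat=np.asarray(Gamma_hat, dtype=float),
        s_gamma=s_gamma,
        s_Gamma=s_Gamma,
        block_assignment=assignment,
    )


def block_identity(block_sizes):
    """Identity BlockLDMatrix over the given block sizes."""
    blocks = []
    start = 0
    for pb in block_sizes:
        blocks.append(((start, start + pb), np.eye(pb)))
        start += pb
    return BlockLDMatrix(blocks, kind="empirical", n_ref=1000)


def block_ld(mats):
    """BlockLDMatrix from a list of correlation matrices."""
    blocks = []
    start = 0
    for mat in mats:
        pb = mat.shape[0]
        blocks.append(((start, start + pb), np.asarray(mat, dtype=float)))
        start += pb
    return BlockLDMatrix(blocks, kind="empirical", n_ref=1000)


def random_instance(rng, p=6, block_sizes=None, corr=0.3):
    """Random small model instance: dataset + LD matrix with AR correlation."""
    if block_sizes is None:
        block_sizes = [p]
    mats = []
    for pb in block_sizes:
        idx = np.arange(pb)
        mats.append(corr ** np.abs(idx[:, None] - idx[None, :]))
    R = block_ld(mats)
    s_g = rng.uniform(0.02, 0.08, p)
    s_G = rng.uniform(0.02, 0.08, p)
    data = toy_dataset(
        gamma_hat=rng.normal(0, 0.1, p),
        Gamma_hat=rng.normal(0, 0.1, p),
        s_gamma=s_g,
        s_Gamma=s_G,
        block_sizes=block_sizes,
    )
    return data, R


@pytest.fixture(scope="session")
def small_sim_dataset():
    """One small simulated study reused by several fitting tests."""
    from mrlink import SimulationConfig, make_dataset

    cfg = SimulationConfig(
        n1=3000, n2=3000, n3=400, M=4, block_size=25,
        rho=0.4, h2_alpha=0.05, beta0=0.1, seed=11,
    )
    return make_dataset(cfg)
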