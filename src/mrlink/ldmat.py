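"""Block-diagonal LD correlation matrices from a reference panel.

LD between SNPs decays with genomic distance, so the genome-wide SNP
correlation matrix is modelled as block-diagonal over a precomputed block
partition (e.g. LDetect output consumed as a BED-like table). Within each
block the empirical dosage correlation from a reference panel is either used
directly or replaced by a sparse positive-definite shrinkage estimate

    R_hat = argmin_{R > 0}  ||R - R_emp||_F^2 / 2  -  tau * log|R|
                            +  lambda * ||offdiag(R)||_1,

where the log-determinant barrier enforces positive definiteness and the
l1 penalty on off-diagonal entries yields sparsity.  The barrier also acts
on the diagonal, which therefore floats slightly above 1; downstream code
must not assume a unit diagonal for shrunk blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BlockLDMatrix",
    "assign_blocks",
    "empirical_block_corr",
    "shrink_block_corr",
    "shrink_objective",
]


@dataclass
class BlockLDMatrix:
    """Block-diagonal SNP correlation estimate.

    Parameters
    ----------
    blocks
        Ordered list of ``((start, stop), matrix)`` pairs; the half-open
        index ranges must partition ``0..p`` without overlap.
    kind
        ``"empirical"`` (unit diagonal) or ``"shrunk"`` (strictly PD,
        diagonal >= 1).
    lam, tau
        Shrinkage tuning parameters (``lam`` = 0 and ``tau`` = 0 for an
        empirical estimate).
    n_ref
        Reference-panel sample size the blocks were estimated from.
    """

    blocks: list[tuple[tuple[int, int], np.ndarray]]
    kind: str = "empirical"
    lam: float = 0.0
    tau: float = 0.0
    n_ref: int = 0

    def __post_init__(self) -> None:
        stop_prev = 0
        for (start, stop), mat in self.blocks:
            if start != stop_prev:
                raise ValueError(f"block ranges do not partition 0..p (gap at {start})")
            if mat.shape != (stop - start, stop - start):
                raise ValueError(f"block matrix shape {mat.shape} != range {(start, stop)}")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ValueError(f"block ({start},{stop}) not symmetric")
            stop_prev = stop

    @property
    def p(self) -> int:
        return self.blocks[-1][0][1] if self.blocks else 0

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, k: int) -> int:
        for b, ((start, stop), _) in enumerate(self.blocks):
            if start <= k < stop:
                return b
        raise IndexError(k)

    def dense(self) -> np.ndarray:
        """Assemble the full block-diagonal matrix (small problems only)."""
        out = np.zeros((self.p, self.p))
        for (start, stop), mat in self.blocks:
            out[start:stop, start:stop] = mat
        return out

    # -- triplet serialization used by the CLI ------------------------------
    def to_files(self, triplet_path, header_path) -> None:
        rows = []
        for b, ((start, stop), mat) in enumerate(self.blocks):
            ii, jj = np.nonzero(np.triu(mat != 0.0))
            for i, j in zip(ii, jj):
                rows.append((b, int(i), int(j), mat[i, j]))
        pd.DataFrame(rows, columns=["block", "i", "j", "value"]).to_csv(
            triplet_path, sep="\t", index=False
        )
        header = {
            "kind": self.kind,
            "lambda": self.lam,
            "tau": self.tau,
            "n_ref": self.n_ref,
            "block_ranges": [[int(s), int(t)] for (s, t), _ in self.blocks],
        }
        with open(header_path, "w") as fh:
            json.dump(header, fh, indent=2)

    @classmethod
    def from_files(cls, triplet_path, header_path) -> "BlockLDMatrix":
        with open(header_path) as fh:
            header = json.load(fh)
        trip = pd.read_csv(triplet_path, sep="\t")
        blocks = []
        for b, (start, stop) in enumerate(header["block_ranges"]):
            pb = stop - start
            mat = np.zeros((pb, pb))
            sub = trip[trip["block"] == b]
            mat[sub["i"], sub["j"]] = sub["value"]
            mat[sub["j"], sub["i"]] = sub["value"]
            blocks.append(((start, stop), mat))
        return cls(
            blocks,
            kind=header["kind"],
            lam=header["lambda"],
            tau=header["tau"],
            n_ref=header["n_ref"],
        )


def assign_blocks(positions: pd.DataFrame, block_table: pd.DataFrame) -> np.ndarray:
    """Map each SNP to the block whose half-open interval contains it.

    Parameters
    ----------
    positions
        Per-SNP table with columns ``chrom`` and ``pos``.
    block_table
        BED-like table with columns ``chrom``, ``start``, ``stop``; rows must
        be non-overlapping within a chromosome.  Intervals are treated as
        half-open ``[start, stop)`` so a SNP sitting exactly on a boundary
        goes to the right-hand block.

    Returns
    -------
    Integer array of block row indices into ``block_table``; ``-1`` marks
    SNPs outside every block (including SNPs on absent chromosomes).
    """
    chroms = positions["chrom"].astype(str).to_numpy()
    pos = positions["pos"].to_numpy()
    out = np.full(len(pos), -1, dtype=int)
    bt = block_table.copy()
    bt["chrom"] = bt["chrom"].astype(str)
    for chrom, sub in bt.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        stops = sub["stop"].to_numpy()
        if np.any(starts[1:] < stops[:-1]):
            raise ValueError(f"overlapping blocks on chromosome {chrom}")
        sel = np.nonzero(chroms == chrom)[0]
        idx = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = (idx >= 0) & (pos[sel] < stops[np.clip(idx, 0, None)])
        out[sel[ok]] = sub.index.to_numpy()[idx[ok]]
    return out


def empirical_block_corr(G_ref: np.ndarray, assignment: np.ndarray) -> BlockLDMatrix:
    """Per-block sample Pearson correlation of reference dosages.

    ``assignment`` must be block-contiguous (SNPs ordered by block), since
    the result is stored as a block-diagonal matrix.  A constant dosage
    column is an error naming the offending SNP.
    """
    G_ref = np.asarray(G_ref, dtype=float)
    n_ref, p = G_ref.shape
    if n_ref < 2:
        raise ValueError("need at least two reference samples")
    sd = G_ref.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"constant dosage column for SNP index {bad}")
    assignment = np.asarray(assignment)
    if np.any(np.diff(assignment) < 0):
        raise ValueError("assignment must be block-contiguous (sort SNPs by block)")
    blocks = []
    start = 0
    for b in np.unique(assignment):
        stop = start + int(np.sum(assignment == b))
        sub = G_ref[:, start:stop]
        if stop - start == 1:
            mat = np.ones((1, 1))
        else:
            mat = np.corrcoef(sub, rowvar=False)
            mat = (mat + mat.T) / 2.0
            np.fill_diagonal(mat, 1.0)
        blocks.append(((start, stop), mat))
        start = stop
    return BlockLDMatrix(blocks, kind="empirical", n_ref=n_ref)


def shrink_objective(R: np.ndarray, R_emp: np.ndarray, lam: float, tau: float) -> float:
    """Value of the shrinkage objective at ``R`` (inf if R not PD)."""
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        return np.inf
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        return np.inf
    off = R - np.diag(np.diag(R))
    return 0.5 * np.sum((R - R_emp) ** 2) - tau * logdet + lam * np.sum(np.abs(off))


def _soft(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def _shrink_one(R_emp: np.ndarray, lam: float, tau: float,
                tol: float = 1e-12, max_iter: int = 20000) -> np.ndarray:
    pb = R_emp.shape[0]
    if pb == 1:
        # scalar closed form: (r - r_emp) - tau / r = 0 with r_emp = 1
        return np.array([[(1.0 + np.sqrt(1.0 + 4.0 * tau)) / 2.0]])

    # PD start: lift the empirical matrix until the smallest eigenvalue is safe
    w = np.linalg.eigvalsh(R_emp)
    R = R_emp.copy()
    if w[0] < 0.05:
        R = R + (0.05 - w[0]) * np.eye(pb)

    def smooth(Rm):
        sign, logdet = np.linalg.slogdet(Rm)
        if sign <= 0:
            return np.inf
        return 0.5 * np.sum((Rm - R_emp) ** 2) - tau * logdet

    def total(Rm):
        off = Rm - np.diag(np.diag(Rm))
        return smooth(Rm) + lam * np.sum(np.abs(off))

    f = smooth(R)
    obj = total(R)
    step = 1.0
    for it in range(max_iter):
        grad = (R - R_emp) - tau * np.linalg.inv(R)
        grad = (grad + grad.T) / 2.0
        # ISTA with backtracking on the smooth part
        while True:
            cand = R - step * grad
            off = _soft(cand - np.diag(np.diag(cand)), step * lam)
            R_new = off + np.diag(np.diag(cand))
            R_new = (R_new + R_new.T) / 2.0
            f_new = smooth(R_new)
            diff = R_new - R
            bound = f + np.sum(grad * diff) + np.sum(diff**2) / (2.0 * step)
            if np.isfinite(f_new) and f_new <= bound + 1e-12:
                break
            step *= 0.5
            if step < 1e-14:
                raise RuntimeError("shrinkage line search failed")
        obj_new = total(R_new)
        rel = abs(obj - obj_new) / max(1.0, abs(obj))
        R, f, obj = R_new, f_new, obj_new
        step = min(step * 1.5, 1.0)
        if rel < tol:
            break
    else:
        raise RuntimeError(
            f"shrinkage did not converge in {max_iter} iterations "
            f"(last relative change {rel:.2e})"
        )
    return R


def shrink_block_corr(R_emp: BlockLDMatrix, lam: float, tau: float = 1e-3) -> BlockLDMatrix:
    """Sparse positive-definite shrinkage of an empirical block LD matrix.

    Solved per block by proximal-gradient (ISTA) iteration with step-size
    backtracking: the Frobenius + log-det part is smooth, the off-diagonal
    l1 penalty is handled by soft-thresholding.  The objective is strongly
    convex (identity Hessian from the Frobenius term plus the PSD barrier
    Hessian), so the iteration converges linearly; we stop at relative
    objective change < 1e-12.

    Default ``tau`` = 1e-3 (the barrier weight is only required to be a
    small positive constant).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    blocks = []
    for b, ((start, stop), mat) in enumerate(R_emp.blocks):
        try:
            shr = _shrink_one(mat, lam, tau)
        except RuntimeError as err:
            raise RuntimeError(f"block {b}: {err}") from err
        blocks.append(((start, stop), shr))
    return BlockLDMatrix(blocks, kind="shrunk", lam=lam, tau=tau, n_ref=R_emp.n_ref)
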