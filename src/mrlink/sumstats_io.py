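"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample MR consumes per-SNP marginal effect sizes and standard errors
from an exposure GWAS and an outcome GWAS, plus a reference panel that fixes
the allele orientation used to estimate LD. All three sources must agree on
which allele each effect is counted for; ``harmonize`` aligns the studies to
the panel's orientation, flipping effect signs where a study reports the
opposite allele and dropping SNPs that cannot be aligned.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import ldmat as _ldmat

__all__ = [
    "SummaryStatsTable",
    "HarmonizedDataset",
    "InstrumentSelection",
    "read_sumstats",
    "read_bim",
    "harmonize",
    "select_instruments",
]

log = logging.getLogger(__name__)

_CANONICAL = ["snp", "chrom", "pos", "a1", "a2", "beta", "se", "n"]
_VALID_ALLELES = {"A", "C", "G", "T"}
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SummaryStatsTable:
    """Validated per-SNP summary statistics.

    Canonical columns: ``snp, chrom, pos, a1, a2, beta, se, n`` where ``a1``
    is the effect allele and ``a2`` the other allele. Constructed through
    :func:`read_sumstats` or :meth:`from_frame`, which drop rows violating
    the invariants (se > 0 and finite, alleles in {A,C,G,T}, unique snp id)
    and log the counts.
    """

    df: pd.DataFrame
    n_dropped: int = 0

    @classmethod
    def from_frame(cls, df: pd.DataFrame, column_map: dict | None = None) -> "SummaryStatsTable":
        if column_map:
            df = df.rename(columns={v: k for k, v in column_map.items()})
        missing = [c for c in _CANONICAL if c not in df.columns]
        if missing:
            raise ValueError(
                f"missing mandatory columns {missing}; columns found: {list(df.columns)}"
            )
        df = df[_CANONICAL].copy()
        df["a1"] = df["a1"].astype(str).str.upper()
        df["a2"] = df["a2"].astype(str).str.upper()
        n0 = len(df)
        ok = (
            pd.to_numeric(df["se"], errors="coerce").gt(0)
            & np.isfinite(pd.to_numeric(df["se"], errors="coerce"))
            & np.isfinite(pd.to_numeric(df["beta"], errors="coerce"))
            & df["a1"].isin(_VALID_ALLELES)
            & df["a2"].isin(_VALID_ALLELES)
        )
        df = df[ok]
        df = df[~df["snp"].duplicated(keep="first")]
        dropped = n0 - len(df)
        if dropped:
            warnings.warn(f"dropped {dropped} invalid summary-statistic rows")
        df = df.reset_index(drop=True)
        df["beta"] = df["beta"].astype(float)
        df["se"] = df["se"].astype(float)
        return cls(df=df, n_dropped=dropped)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.df)


def read_sumstats(path, column_map: dict | None = None, sep: str = "\t") -> SummaryStatsTable:
    """Read a delimited summary-statistics file with a header row.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"snp": "rsid", "beta": "b"}``; unmapped canonical names must be
    present verbatim.
    """
    df = pd.read_csv(path, sep=sep)
    return SummaryStatsTable.from_frame(df, column_map=column_map)


@dataclass
class HarmonizedDataset:
    """Exposure/outcome effects aligned to a common allele orientation.

    ``gamma_hat``/``s_gamma`` are the SNP-exposure marginal effects and
    standard errors, ``Gamma_hat``/``s_Gamma`` the SNP-outcome ones; all are
    oriented to the reference panel's allele coding and ordered by
    (chrom, pos). ``block_assignment`` maps every SNP to an LD block.
    """

    snp: pd.DataFrame  # columns snp, chrom, pos, a1, a2
    gamma_hat: np.ndarray
    s_gamma: np.ndarray
    Gamma_hat: np.ndarray
    s_Gamma: np.ndarray
    block_assignment: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.snp)
        for name in ("gamma_hat", "s_gamma", "Gamma_hat", "s_Gamma", "block_assignment"):
            arr = np.asarray(getattr(self, name), dtype=float if name != "block_assignment" else int)
            if arr.shape != (p,):
                raise ValueError(f"{name} has length {arr.shape}, expected ({p},)")
            setattr(self, name, arr)
        if np.any(self.s_gamma <= 0) or np.any(self.s_Gamma <= 0):
            raise ValueError("standard errors must be positive")
        if np.any(self.block_assignment < 0):
            raise ValueError("block assignment must be total (no unassigned SNPs)")

    @property
    def p(self) -> int:
        return len(self.snp)

    def to_frame(self) -> pd.DataFrame:
        out = self.snp.copy().reset_index(drop=True)
        out["gamma_hat"] = self.gamma_hat
        out["s_gamma"] = self.s_gamma
        out["Gamma_hat"] = self.Gamma_hat
        out["s_Gamma"] = self.s_Gamma
        out["block"] = self.block_assignment
        return out

    def write(self, tsv_path, sidecar_path=None, **provenance) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if sidecar_path is not None:
            blocks = {}
            for b in np.unique(self.block_assignment):
                idx = np.nonzero(self.block_assignment == b)[0]
                blocks[int(b)] = [int(idx[0]), int(idx[-1]) + 1]
            with open(sidecar_path, "w") as fh:
                json.dump({"block_ranges": blocks, **provenance}, fh, indent=2)

    @classmethod
    def read(cls, tsv_path) -> "HarmonizedDataset":
        df = pd.read_csv(tsv_path, sep="\t")
        return cls(
            snp=df[["snp", "chrom", "pos", "a1", "a2"]],
            gamma_hat=df["gamma_hat"].to_numpy(),
            s_gamma=df["s_gamma"].to_numpy(),
            Gamma_hat=df["Gamma_hat"].to_numpy(),
            s_Gamma=df["s_Gamma"].to_numpy(),
            block_assignment=df["block"].to_numpy(),
        )


def _orient(study: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Flip a study's effects onto the panel's allele orientation.

    Returns rows whose allele pair matches the panel's either directly or
    swapped (beta negated); everything else is dropped.
    """
    m = study.merge(panel[["snp", "a1", "a2"]], on="snp", suffixes=("", "_panel"))
    same = (m["a1"] == m["a1_panel"]) & (m["a2"] == m["a2_panel"])
    swap = (m["a1"] == m["a2_panel"]) & (m["a2"] == m["a1_panel"])
    m.loc[swap, "beta"] = -m.loc[swap, "beta"]
    m.loc[swap, ["a1", "a2"]] = m.loc[swap, ["a2", "a1"]].to_numpy()
    return m[same | swap][_CANONICAL]


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    panel_alleles: pd.DataFrame,
    block_table: pd.DataFrame | None = None,
    keep_ambiguous: bool = False,
) -> HarmonizedDataset:
    """Align exposure and outcome studies to the panel allele orientation.

    Takes the intersection of the three SNP sets; sign-flips effect sizes
    where a study's effect allele is the panel's other allele; drops SNPs
    whose allele set cannot be matched even after swapping, and (by default)
    strand-ambiguous A/T and C/G SNPs, whose orientation cannot be resolved
    without strand information. Output is ordered by (chrom, pos).

    ``panel_alleles`` needs columns ``snp, a1, a2`` (e.g. from a PLINK .bim);
    ``block_table`` is a BED-like (chrom, start, stop) table — when omitted,
    each chromosome forms a single block.
    """
    panel = panel_alleles.copy()
    panel["a1"] = panel["a1"].astype(str).str.upper()
    panel["a2"] = panel["a2"].astype(str).str.upper()
    if not keep_ambiguous:
        amb = [tuple(x) in _AMBIGUOUS for x in panel[["a1", "a2"]].to_numpy()]
        panel = panel[~np.asarray(amb)]
    if panel.empty:
        raise ValueError("no usable panel alleles")

    def dedup(df):
        # duplicates resolved by keeping the smallest-SE record
        return df.sort_values("se").drop_duplicates("snp").sort_index()

    exp = _orient(dedup(exposure.df), panel)
    out = _orient(dedup(outcome.df), panel)
    merged = exp.merge(out, on="snp", suffixes=("_exp", "_out"))
    if merged.empty:
        raise ValueError("empty SNP intersection after harmonization")
    merged = merged.sort_values(["chrom_exp", "pos_exp"], kind="stable").reset_index(drop=True)

    meta = merged[["snp", "chrom_exp", "pos_exp", "a1_exp", "a2_exp"]].rename(
        columns={"chrom_exp": "chrom", "pos_exp": "pos", "a1_exp": "a1", "a2_exp": "a2"}
    )
    if block_table is not None:
        assignment = _ldmat.assign_blocks(meta[["chrom", "pos"]], block_table)
        keep = assignment >= 0
        if not np.all(keep):
            warnings.warn(f"dropping {int((~keep).sum())} SNPs outside all LD blocks")
            meta = meta[keep].reset_index(drop=True)
            merged = merged[keep].reset_index(drop=True)
            assignment = assignment[keep]
        # renumber blocks in order of first appearance
        _, assignment = np.unique(assignment, return_inverse=True)
    else:
        _, assignment = np.unique(meta["chrom"].astype(str), return_inverse=True)

    return HarmonizedDataset(
        snp=meta,
        gamma_hat=merged["beta_exp"].to_numpy(),
        s_gamma=merged["se_exp"].to_numpy(),
        Gamma_hat=merged["beta_out"].to_numpy(),
        s_Gamma=merged["se_out"].to_numpy(),
        block_assignment=assignment,
    )


def read_bim(path) -> pd.DataFrame:
    """Read a PLINK .bim file into a panel-allele table.

    Returns columns ``snp, chrom, pos, a1, a2`` usable as the
    ``panel_alleles`` argument of :func:`harmonize` (PLINK's A1 is the
    counted allele).
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    return df[["snp", "chrom", "pos", "a1", "a2"]]


@dataclass
class InstrumentSelection:
    """SNP ids passing a marginal-association screen, with the cutoff used."""

    snps: set
    threshold: float


def select_instruments(screening: SummaryStatsTable, threshold: float = 1e-4) -> InstrumentSelection:
    """Select instruments from an independent screening study.

    Keeps SNPs whose two-sided Wald p-value (beta/se against a standard
    normal) falls below ``threshold``. The screening study must be a third
    dataset independent of both exposure and outcome; selecting on the
    exposure study itself induces selection (winner's curse) bias.
    """
    z = screening.df["beta"].to_numpy() / screening.df["se"].to_numpy()
    pval = 2.0 * stats.norm.sf(np.abs(z))
    keep = screening.df["snp"][pval < threshold]
    return InstrumentSelection(snps=set(keep), threshold=threshold)
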