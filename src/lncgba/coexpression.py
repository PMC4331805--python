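"""lncRNA-mRNA co-expression network construction.

For every (lncRNA, protein-coding) gene pair the sample Pearson
correlation r of their expression profiles across conditions is
computed, together with the exact two-sided significance test for a
bivariate-normal correlation,

    t = r * sqrt(n - 2) / sqrt(1 - r**2),   t ~ t(n - 2) under r = 0,

where n is the number of conditions.  Raw p-values are adjusted over
the full lncRNA x coding family (Benjamini-Hochberg by default: the
pairs are treated as approximately independent tests) and an edge is
retained when |r| > r_cutoff (default 0.9, strict) and the adjusted
p-value < alpha (default 0.05, strict).

Pairs in which either profile has zero variance are dropped — the
correlation is undefined there — and the dropped count is logged.
The computation is blocked over lncRNA rows so memory stays
proportional to one block; results are identical for any block size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionEdge",
    "CoexpressionNetwork",
    "CoexpressionNetworkBuilder",
    "pearson_r",
    "pearson_pvalue",
    "all_pairs",
    "adjust_and_filter",
    "coexpressed_set",
]

PAIR_COLUMNS = ["lncrna_id", "coding_id", "r", "p_raw"]
EDGE_COLUMNS = ["lncrna_id", "coding_id", "r", "p_raw", "p_adj"]


@dataclass(frozen=True)
class CoexpressionEdge:
    """One significant lncRNA-coding pair."""

    lncrna_id: str
    coding_id: str
    r: float
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if abs(self.r) > 1:
            raise ValueError(f"|r| > 1: {self.r}")
        if self.p_adj < self.p_raw:
            raise ValueError("adjusted p below raw p")


class CoexpressionNetwork:
    """Significant co-expression edges plus the condition count behind them.

    Parameters
    ----------
    edges:
        DataFrame with columns ``lncrna_id, coding_id, r, p_raw, p_adj``;
        (lncrna_id, coding_id) pairs must be unique.
    n_conditions:
        Number of conditions the correlations were computed over.
    """

    def __init__(self, edges: pd.DataFrame, n_conditions: int) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns: {missing}")
        if edges.duplicated(subset=["lncrna_id", "coding_id"]).any():
            raise ValueError("duplicate (lncrna_id, coding_id) edge")
        self.edges = edges.reset_index(drop=True)
        self.n_conditions = int(n_conditions)
        self._adjacency: dict[str, set[str]] = {}
        for lnc, coding in zip(edges["lncrna_id"], edges["coding_id"]):
            self._adjacency.setdefault(lnc, set()).add(coding)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def lncrna_ids(self) -> set[str]:
        return set(self._adjacency)

    def coexpressed_set(self, lncrna_id: str) -> set[str]:
        """Coding genes significantly co-expressed with one lncRNA."""
        if lncrna_id not in self._adjacency:
            logger.warning("lncRNA %r not present in the network", lncrna_id)
            return set()
        return set(self._adjacency[lncrna_id])

    def to_tsv(self, path: str | Path) -> None:
        """Write edges as TSV with 17-significant-digit numeric columns."""
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path, n_conditions: int) -> "CoexpressionNetwork":
        return cls(pd.read_csv(path, sep="\t"), n_conditions)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation, clamped to [-1, 1] against rounding.

    Both vectors must have equal length >= 3 and nonzero variance;
    a zero-variance vector raises ``ValueError`` ("undefined
    correlation") so the caller can drop the pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0 or sy == 0:
        raise ValueError("undefined correlation: zero-variance vector")
    return float(np.clip(np.dot(xc, yc) / (sx * sy), -1.0, 1.0))


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a sample correlation r over n observations.

    Uses the exact t-test with n - 2 degrees of freedom; r = +-1 maps
    to p = 0 exactly (degenerate bound of the statistic).
    """
    if n < 3:
        raise ValueError("need n >= 3 conditions for the significance test")
    if abs(r) > 1:
        raise ValueError(f"|r| > 1: {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _pvalues_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorised two-sided t-test p-values; |r| = 1 maps to exactly 0."""
    r = np.clip(r, -1.0, 1.0)
    out = np.zeros_like(r)
    interior = np.abs(r) < 1.0
    ri = r[interior]
    t = ri * np.sqrt(n - 2) / np.sqrt(1.0 - ri * ri)
    # survival function of t(n-2) via the regularised incomplete beta
    df = n - 2
    out[interior] = special.betainc(df / 2.0, 0.5, df / (df + t * t))
    return out


def all_pairs(
    lnc: ExpressionMatrix,
    coding: ExpressionMatrix,
    block_size: int = 256,
) -> pd.DataFrame:
    """Correlate every lncRNA against every coding gene.

    Returns a DataFrame ``(lncrna_id, coding_id, r, p_raw)`` in
    lexicographic (lncrna_id, coding_id) order containing
    ``|lnc| * |coding|`` rows minus the pairs dropped because one
    profile had zero variance (the dropped count is logged).  Both
    matrices must share the same ordered condition set.
    """
    if lnc.condition_ids != coding.condition_ids:
        raise ValueError("lncRNA and coding matrices have different conditions")
    if lnc.n_genes == 0 or coding.n_genes == 0:
        raise ValueError("empty expression matrix")
    n = lnc.n_conditions

    lnc_order = sorted(range(lnc.n_genes), key=lambda i: lnc.gene_ids[i])
    coding_order = sorted(range(coding.n_genes), key=lambda j: coding.gene_ids[j])
    lx = lnc.values[lnc_order]
    cx = coding.values[coding_order]
    lnc_names = np.asarray(lnc.gene_ids, dtype=object)[lnc_order]
    coding_names = np.asarray(coding.gene_ids, dtype=object)[coding_order]

    lxc = lx - lx.mean(axis=1, keepdims=True)
    cxc = cx - cx.mean(axis=1, keepdims=True)
    lnorm = np.sqrt((lxc * lxc).sum(axis=1))
    cnorm = np.sqrt((cxc * cxc).sum(axis=1))
    lnc_ok = lnorm > 0
    coding_ok = cnorm > 0
    dropped = int((~lnc_ok).sum()) * len(coding_names) + int(
        lnc_ok.sum()
    ) * int((~coding_ok).sum())
    if dropped:
        logger.warning("all_pairs: dropped %d zero-variance pair(s)", dropped)

    cxc_ok = cxc[coding_ok]
    cnorm_ok = cnorm[coding_ok]
    coding_names_ok = coding_names[coding_ok]
    chunks: list[pd.DataFrame] = []
    for start in range(0, len(lnc_names), block_size):
        rows = slice(start, start + block_size)
        ok = lnc_ok[rows]
        if not ok.any():
            continue
        block = lxc[rows][ok]
        norms = lnorm[rows][ok]
        names = lnc_names[rows][ok]
        r = (block @ cxc_ok.T) / np.outer(norms, cnorm_ok)
        r = np.clip(r, -1.0, 1.0)
        p = _pvalues_from_r(r.ravel(), n)
        chunks.append(
            pd.DataFrame(
                {
                    "lncrna_id": np.repeat(names, len(coding_names_ok)),
                    "coding_id": np.tile(coding_names_ok, len(names)),
                    "r": r.ravel(),
                    "p_raw": p,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(chunks, ignore_index=True)


def adjust_and_filter(
    pairs: pd.DataFrame,
    n_conditions: int,
    r_cutoff: float = 0.9,
    alpha: float = 0.05,
    method: str = "bh",
) -> CoexpressionNetwork:
    """Adjust raw p-values over the whole pair family and keep edges.

    Adjustment treats ALL tested pairs as one family.  An edge is kept
    when |r| > r_cutoff and adjusted p < alpha, both strict, matching
    the significance rule of the annotation workflow.
    """
    from .enrichment import benjamini_hochberg, benjamini_yekutieli

    if len(pairs) == 0:
        raise ValueError("no pairs to adjust")
    adjusters = {"bh": benjamini_hochberg, "by": benjamini_yekutieli}
    if method not in adjusters:
        raise ValueError(f"unknown adjustment method {method!r}")
    p_adj = adjusters[method](pairs["p_raw"].to_numpy())
    keep = (np.abs(pairs["r"].to_numpy()) > r_cutoff) & (p_adj < alpha)
    edges = pairs.loc[keep, PAIR_COLUMNS].copy()
    edges["p_adj"] = p_adj[keep]
    logger.info(
        "adjust_and_filter: kept %d of %d pairs (|r| > %g, adjusted p < %g)",
        len(edges), len(pairs), r_cutoff, alpha,
    )
    return CoexpressionNetwork(edges.reset_index(drop=True), n_conditions)


def coexpressed_set(network: CoexpressionNetwork, lncrna_id: str) -> set[str]:
    """Module-level alias for :meth:`CoexpressionNetwork.coexpressed_set`."""
    return network.coexpressed_set(lncrna_id)


class CoexpressionNetworkBuilder(BaseEstimator):
    """Estimator building the significant co-expression network.

    Parameters
    ----------
    r_cutoff:
        Minimum |Pearson r| (strict) for a significant pair.
    alpha:
        Adjusted-p threshold (strict).
    method:
        Multiple-testing adjustment over the full pair family,
        ``"bh"`` (Benjamini-Hochberg, default) or ``"by"``.
    block_size:
        lncRNA rows correlated per block; affects memory only.

    Attributes
    ----------
    network_ : CoexpressionNetwork
        Significant edges after adjustment and filtering.
    n_pairs_tested_ : int
        Pairs entering the multiple-testing family.
    n_conditions_ : int
        Conditions shared by the two input matrices.
    """

    def __init__(
        self,
        r_cutoff: float = 0.9,
        alpha: float = 0.05,
        method: str = "bh",
        block_size: int = 256,
    ) -> None:
        self.r_cutoff = r_cutoff
        self.alpha = alpha
        self.method = method
        self.block_size = block_size

    def fit(
        self, lnc: ExpressionMatrix, coding: ExpressionMatrix
    ) -> "CoexpressionNetworkBuilder":
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.r_cutoff < 1:
            raise ValueError("r_cutoff must be in [0, 1)")
        pairs = all_pairs(lnc, coding, block_size=self.block_size)
        self.n_pairs_tested_ = len(pairs)
        self.n_conditions_ = lnc.n_conditions
        self.network_ = adjust_and_filter(
            pairs,
            n_conditions=lnc.n_conditions,
            r_cutoff=self.r_cutoff,
            alpha=self.alpha,
            method=self.method,
        )
        return self

    def transform(self, lncrna_ids: Iterable[str]) -> dict[str, set[str]]:
        """Map each queried lncRNA to its co-expressed coding-gene set."""
        if not hasattr(self, "network_"):
            raise RuntimeError("builder is not fitted")
        return {l: self.network_.coexpressed_set(l) for l in lncrna_ids}
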