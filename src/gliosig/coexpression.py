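"""Anchor-gene co-expression ranking.

The signature-derivation workflow starts from a single anchor gene (an S100A
family member in the motivating application) and collects the cluster of
genes most strongly co-expressed with it across a cohort, ranked by Spearman
correlation. The cluster keeps "at least k" members: ties at the rank-k
boundary are all included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix, GeneSet, GliosigWarning

__all__ = [
    "UndefinedCorrelationError",
    "CorrelationRanking",
    "spearman_correlation",
    "pearson_correlation",
    "rank_coexpressed",
]

DIRECTIONS = ("positive", "negative", "absolute")


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (zero-variance input)."""


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"inputs must be equal-length 1-D vectors, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    return x, y


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks. Raises :class:`UndefinedCorrelationError`
    when either input is constant.
    """
    x, y = _check_pair(x, y)
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation on raw values."""
    x, y = _check_pair(x, y)
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class CorrelationRanking:
    """Genes ranked by correlation with an anchor gene.

    ``entries`` is sorted non-increasingly by the direction's criterion
    (rho, -rho, or |rho|); the anchor never appears in it.
    """

    anchor: str
    entries: tuple[tuple[str, float, int], ...]
    direction: str

    def genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def gene_set(self, name: str | None = None) -> GeneSet:
        return GeneSet(
            name=name or f"coexpr_{self.anchor}_{self.direction}",
            description=f"genes co-expressed with {self.anchor} ({self.direction} Spearman)",
            genes=frozenset(self.genes()),
            empty_allowed=True,
        )

    def __len__(self) -> int:
        return len(self.entries)


def _criterion(rho: np.ndarray, direction: str) -> np.ndarray:
    if direction == "positive":
        return rho
    if direction == "negative":
        return -rho
    return np.abs(rho)


def rank_coexpressed(
    matrix: ExpressionMatrix,
    anchor: str,
    k: int = 500,
    direction: str = "positive",
) -> CorrelationRanking:
    """Rank all genes by Spearman correlation with ``anchor`` and keep the top k.

    All genes tied with the rank-k boundary value are included, so the
    returned cluster has *at least* k members. Zero-variance genes are
    skipped with a warning; the anchor is excluded from its own ranking.

    Parameters
    ----------
    k:
        Minimum cluster size (default 500, the conventional cluster size for
        this workflow). If k exceeds the number of scorable candidates, all
        candidates are returned.
    direction:
        ``positive`` ranks by rho, ``negative`` by -rho, ``absolute`` by |rho|.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if anchor not in matrix:
        raise KeyError(f"anchor gene {anchor!r} not in expression matrix")
    values = matrix.data.to_numpy(dtype=float)
    n_samples = values.shape[1]
    if n_samples < 3:
        raise ValueError(f"need at least 3 samples, got {n_samples}")

    genes = np.asarray(matrix.gene_ids)
    anchor_idx = int(np.flatnonzero(genes == anchor)[0])
    anchor_vals = values[anchor_idx]
    if np.ptp(anchor_vals) == 0:
        raise UndefinedCorrelationError(f"anchor {anchor!r} has zero variance")

    variable = np.ptp(values, axis=1) > 0
    variable[anchor_idx] = False
    n_const = int((~variable).sum()) - 1
    if n_const > 0:
        warnings.warn(
            f"{n_const} zero-variance genes skipped in co-expression ranking",
            GliosigWarning,
            stacklevel=2,
        )

    # Spearman = Pearson on mid-ranks; vectorized over all candidate rows.
    ranks = stats.rankdata(values[variable], axis=1)
    anchor_ranks = stats.rankdata(anchor_vals)
    ar = anchor_ranks - anchor_ranks.mean()
    rr = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((rr**2).sum(axis=1)) * np.sqrt((ar**2).sum())
    rho = (rr @ ar) / denom

    cand_genes = genes[variable]
    crit = _criterion(rho, direction)
    # sort by criterion descending, gene name ascending for determinism
    order = np.lexsort((cand_genes, -crit))
    crit_sorted = crit[order]
    if k >= len(order):
        keep = len(order)
    else:
        boundary = crit_sorted[k - 1]
        keep = int(np.searchsorted(-crit_sorted, -boundary, side="right"))
    idx = order[:keep]
    entries = tuple(
        (str(cand_genes[i]), float(rho[i]), n_samples) for i in idx
    )
    return CorrelationRanking(anchor=anchor, entries=entries, direction=direction)
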