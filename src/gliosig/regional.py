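"""Anatomical-region expression profiles and region-upregulated gene calling.

Region-dissected glioblastoma RNA-seq (one region label per sample, drawn
from LE / IT / CT / MVP / PAN) supports two questions: what does each gene's
regional mean profile look like, and which genes are upregulated in a chosen
set of target regions relative to the rest of the tumor? Upregulation is
called per gene with a Mann-Whitney U test (target vs rest), Benjamini-
Hochberg correction across genes, and a log2 fold-change floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import REGIONS, ExpressionMatrix, GeneSet

__all__ = [
    "RegionProfileTable",
    "region_mean_profile",
    "mann_whitney_u",
    "region_upregulated_genes",
]


@dataclass(frozen=True)
class RegionProfileTable:
    """Per-gene per-region mean log2 expression, plus sample counts per region."""

    means: pd.DataFrame  # genes x regions
    n_per_region: dict[str, int]


def region_mean_profile(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> RegionProfileTable:
    """Arithmetic mean log2 expression of every gene in every labelled region.

    Every sample in ``matrix`` must carry a region label in ``metadata``.
    Regions absent from the metadata are omitted from the profile.
    """
    meta = metadata.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    labels = meta.loc[matrix.sample_ids, "region"]
    if labels.isna().any():
        bad = labels.index[labels.isna()].tolist()
        raise ValueError(f"samples without region label: {bad[:5]}")
    present = [r for r in REGIONS if (labels == r).any()]
    means = pd.DataFrame(
        {r: matrix.data.loc[:, (labels == r).to_numpy()].mean(axis=1) for r in present}
    )
    counts = {r: int((labels == r).sum()) for r in present}
    return RegionProfileTable(means=means, n_per_region=counts)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U of group ``a`` vs ``b`` with a two-sided p-value.

    Mid-ranks handle ties. The p-value is exact when the pooled sample is
    small (n_a + n_b <= 12) and tie-free, otherwise it comes from the normal
    approximation with tie and continuity corrections. Returns ``(U_a, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence either way
        return float(a.size * b.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    if u == a.size * b.size / 2.0:
        # perfectly balanced rank evidence (e.g. identical group multisets)
        return u, 1.0
    return u, float(min(res.pvalue, 1.0))


def _vectorized_mwu(target: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Two-sided asymptotic Mann-Whitney p per gene (rows), with tie handling."""
    res = stats.mannwhitneyu(target, rest, alternative="two-sided",
                             method="asymptotic", axis=-1)
    return np.minimum(np.nan_to_num(res.pvalue, nan=1.0), 1.0)


def region_upregulated_genes(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    target_regions,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> tuple[GeneSet, pd.DataFrame]:
    """Call genes upregulated in ``target_regions`` vs all other regions.

    Per gene: Mann-Whitney U of target-region samples against the rest,
    BH correction across genes; a gene passes iff ``q < alpha`` and its log2
    fold change (target mean - rest mean) is at least ``lfc_min``.

    Returns the passing :class:`GeneSet` and the full per-gene results table
    (columns: gene, lfc, U, p, q, passed).
    """
    target_regions = tuple(target_regions)
    if not target_regions:
        raise ValueError("target_regions must be non-empty")
    unknown = [r for r in target_regions if r not in REGIONS]
    if unknown:
        raise ValueError(f"unknown target regions {unknown}; vocabulary is {REGIONS}")

    meta = metadata.set_index("sample_id")
    labels = meta.loc[matrix.sample_ids, "region"]
    in_target = labels.isin(target_regions).to_numpy()
    labelled = labels.notna().to_numpy()
    in_rest = labelled & ~in_target
    for r in target_regions:
        if not (labels == r).any():
            raise ValueError(f"target region {r!r} has no samples")
    if in_target.sum() < 2 or in_rest.sum() < 2:
        raise ValueError(
            f"need >= 2 samples per side, got {int(in_target.sum())} target / "
            f"{int(in_rest.sum())} rest"
        )

    values = matrix.data.to_numpy(dtype=float)
    tgt = values[:, in_target]
    rst = values[:, in_rest]
    lfc = tgt.mean(axis=1) - rst.mean(axis=1)

    n1, n2 = tgt.shape[1], rst.shape[1]
    if n1 + n2 > 12:
        pooled = np.concatenate([tgt, rst], axis=1)
        constant = np.ptp(pooled, axis=1) == 0
        p = np.ones(values.shape[0])
        u = np.full(values.shape[0], n1 * n2 / 2.0)
        if (~constant).any():
            res = stats.mannwhitneyu(
                tgt[~constant], rst[~constant], alternative="two-sided",
                method="asymptotic", axis=-1,
            )
            p[~constant] = np.minimum(np.nan_to_num(res.pvalue, nan=1.0), 1.0)
            u[~constant] = res.statistic
    else:
        u = np.empty(values.shape[0])
        p = np.empty(values.shape[0])
        for i in range(values.shape[0]):
            u[i], p[i] = mann_whitney_u(tgt[i], rst[i])

    _, q, _, _ = multipletests(p, method="fdr_bh")
    passed = (q < alpha) & (lfc >= lfc_min)
    results = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "lfc": lfc,
            "U": u,
            "p": p,
            "q": q,
            "passed": passed,
        }
    )
    gene_set = GeneSet(
        name="region_up_" + "_".join(target_regions),
        description=(
            f"genes upregulated in {'+'.join(target_regions)} vs rest "
            f"(q<{alpha}, lfc>={lfc_min})"
        ),
        genes=frozenset(results.loc[passed, "gene"]),
        empty_allowed=True,
    )
    return gene_set, results
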