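"""Spatial-inflammation signature derivation and single-sample scoring.

A signature is the three-way intersection of (i) the anchor gene's
co-expression cluster, (ii) an inflammation annotation gene set, and (iii)
genes upregulated in the designated anatomical regions. Samples are scored
with the mean per-gene z-score of the signature genes, and scores are
stratified into high/low groups at a median or quantile cutpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, GliosigWarning

__all__ = [
    "SignatureDefinition",
    "ScoreVector",
    "derive_signature",
    "zscore_by_gene",
    "score_samples",
    "stratify",
]


@dataclass(frozen=True)
class SignatureDefinition:
    """A derived signature with full provenance of its three input sets."""

    name: str
    anchor: str
    genes: GeneSet
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def derive_signature(
    coexpr: GeneSet,
    inflammation: GeneSet,
    regional: GeneSet,
    name: str,
    anchor: str,
    include_anchor: bool = False,
) -> SignatureDefinition:
    """Intersect co-expression, inflammation-annotation and region-up sets.

    An empty intersection is allowed but reported with a warning (the result
    can then not be scored). ``include_anchor=True`` re-appends the anchor
    gene to the derived signature; by default the anchor, whose
    self-correlation carries no information, stays out.
    """
    genes = coexpr.genes & inflammation.genes & regional.genes
    if include_anchor:
        genes = genes | {anchor}
    if not genes:
        warnings.warn(
            f"signature {name!r}: empty intersection of "
            f"{coexpr.name!r}, {inflammation.name!r}, {regional.name!r}",
            GliosigWarning,
            stacklevel=2,
        )
    provenance = {
        "inputs": {
            coexpr.name: len(coexpr),
            inflammation.name: len(inflammation),
            regional.name: len(regional),
        },
        "pairwise": {
            f"{coexpr.name}&{inflammation.name}": len(coexpr.genes & inflammation.genes),
            f"{coexpr.name}&{regional.name}": len(coexpr.genes & regional.genes),
            f"{inflammation.name}&{regional.name}": len(inflammation.genes & regional.genes),
        },
        "intersection": len(genes),
        "anchor_included": include_anchor,
    }
    return SignatureDefinition(
        name=name,
        anchor=anchor,
        genes=GeneSet(name=name, description=f"anchor {anchor}", genes=genes,
                      empty_allowed=True),
        provenance=provenance,
    )


def zscore_by_gene(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene across samples: (x - mean) / sd, sd with ddof=1.

    Zero-variance genes cannot be standardized and are dropped with a
    warning.
    """
    values = matrix.data
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance genes dropped in z-scoring",
            GliosigWarning,
            stacklevel=2,
        )
        values = values.loc[~constant]
        sd = sd.loc[~constant]
    z = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z)


@dataclass(frozen=True)
class ScoreVector:
    """Per-sample signature score: mean of per-gene z-scores (dimensionless)."""

    scores: pd.Series
    signature_name: str
    n_genes_used: int
    missing_genes: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.scores)


def score_samples(matrix: ExpressionMatrix, signature: SignatureDefinition) -> ScoreVector:
    """Score every sample as the mean z-scored expression of signature genes.

    Signature genes absent from the matrix are dropped with a warning; at
    least one must be present.
    """
    present = [g for g in signature.genes if g in matrix]
    missing = tuple(g for g in signature.genes if g not in matrix)
    if not present:
        raise ValueError(
            f"no genes of signature {signature.name!r} present in the matrix"
        )
    if missing:
        warnings.warn(
            f"signature {signature.name!r}: {len(missing)} genes missing from matrix",
            GliosigWarning,
            stacklevel=2,
        )
    z = zscore_by_gene(matrix)
    present = [g for g in present if g in z]
    scores = z.data.loc[present].mean(axis=0)
    return ScoreVector(
        scores=scores,
        signature_name=signature.name,
        n_genes_used=len(present),
        missing_genes=missing,
    )


def stratify(scores: ScoreVector | pd.Series, rule: str = "median", q: float = 0.5) -> pd.Series:
    """Split samples into high/low groups at a score cutpoint.

    ``rule`` is ``"median"`` or ``"quantile"`` (with quantile level ``q``).
    A sample is *high* iff its score is strictly above the cutpoint; scores
    equal to the cutpoint go to *low* (deterministic tie-break). Raises if
    all scores are identical.
    """
    s = scores.scores if isinstance(scores, ScoreVector) else scores
    if len(s) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if s.nunique() == 1:
        raise ValueError("all scores identical; stratification undefined")
    if rule == "median":
        cut = float(s.median())
    elif rule == "quantile":
        if not 0 < q < 1:
            raise ValueError(f"quantile level must be in (0,1), got {q}")
        cut = float(s.quantile(q))
    else:
        raise ValueError(f"rule must be 'median' or 'quantile', got {rule!r}")
    return pd.Series(np.where(s > cut, "high", "low"), index=s.index, name="group")
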