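"""Paired control-vs-treated response quantification.

Two input layouts are supported: qPCR Ct tables, reduced to per-gene fold
changes by the delta-delta Ct method against a reference gene, and paired
expression profiles, reduced to per-gene log2 fold changes directly. Per
subject, a responder is called when the signature genes' log2 fold changes
are collectively shifted below zero by a one-sided Wilcoxon signed-rank test
(the drug is expected to *reduce* the inflammation signatures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix
from .signature import SignatureDefinition

__all__ = [
    "ResponseCall",
    "delta_delta_ct",
    "signature_response",
    "paired_log2_fold_changes",
    "count_responders",
]

DEFAULT_REFERENCE_GENES = ("GAPDH", "Gapdh")


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_gene: str,
    target_genes=None,
) -> pd.DataFrame:
    """Relative quantification of qPCR data by the delta-delta Ct method.

    Replicate Ct values are averaged (arithmetic mean) per
    (subject, condition, gene); then per condition
    ``dCt = Ct_target - Ct_reference``, ``ddCt = dCt_treated - dCt_control``
    and ``fold = 2 ** (-ddCt)``.

    Returns one row per (subject, gene) with columns
    ``subject_id, gene, dct_control, dct_treated, ddct, fold``.
    """
    means = (
        ct.groupby(["subject_id", "condition", "gene"], sort=True)["ct"]
        .mean()
        .unstack("condition")
    )
    for cond in ("control", "treated"):
        if cond not in means.columns:
            raise ValueError(f"no {cond!r} measurements in Ct table")
    rows = []
    for subject, block in means.groupby(level="subject_id", sort=True):
        block = block.droplevel("subject_id")
        if reference_gene not in block.index:
            raise ValueError(f"reference gene {reference_gene!r} missing for subject {subject!r}")
        ref = block.loc[reference_gene]
        if ref.isna().any():
            missing = ref.index[ref.isna()].tolist()
            raise ValueError(
                f"reference gene {reference_gene!r} missing in condition(s) "
                f"{missing} for subject {subject!r}"
            )
        genes = [g for g in block.index if g != reference_gene]
        if target_genes is not None:
            wanted = set(target_genes)
            genes = [g for g in genes if g in wanted]
        for gene in genes:
            row = block.loc[gene]
            if row.isna().any():
                missing = row.index[row.isna()].tolist()
                raise ValueError(
                    f"gene {gene!r} missing in condition(s) {missing} for subject {subject!r}"
                )
            dct_c = row["control"] - ref["control"]
            dct_t = row["treated"] - ref["treated"]
            ddct = dct_t - dct_c
            rows.append((subject, gene, dct_c, dct_t, ddct, 2.0 ** (-ddct)))
    return pd.DataFrame(
        rows, columns=["subject_id", "gene", "dct_control", "dct_treated", "ddct", "fold"]
    )


@dataclass(frozen=True)
class ResponseCall:
    """Per-subject treatment response over the signature genes."""

    subject_id: str
    delta_score: float  # mean log2 fold change over usable signature genes
    statistic: float
    p: float
    responder: bool
    n_genes: int
    rule: str


def signature_response(
    log2_fold_changes,
    subject_id: str,
    alpha: float = 0.05,
) -> ResponseCall:
    """Call a subject's response from signature-gene log2 fold changes.

    One-sided Wilcoxon signed-rank of the fold changes against zero
    (alternative: decrease under treatment); the subject is a responder iff
    ``p < alpha``. Exact null when at most 15 nonzero genes, normal
    approximation otherwise. Requires >= 3 usable genes. All-zero fold
    changes are a degenerate no-change case: non-responder with p = 1.
    """
    fc = np.asarray(
        log2_fold_changes.to_numpy() if isinstance(log2_fold_changes, pd.Series)
        else log2_fold_changes,
        dtype=float,
    )
    if fc.size < 3:
        raise ValueError(
            f"subject {subject_id!r}: need >= 3 signature genes with fold changes, got {fc.size}"
        )
    rule = f"one-sided Wilcoxon signed-rank (decrease), p < {alpha}"
    nonzero = fc[fc != 0]
    if nonzero.size == 0:
        return ResponseCall(
            subject_id=subject_id, delta_score=0.0, statistic=float("nan"),
            p=1.0, responder=False, n_genes=fc.size, rule=rule + " [no change]",
        )
    method = "exact" if nonzero.size <= 15 and len(np.unique(np.abs(nonzero))) == nonzero.size \
        else "approx"
    res = stats.wilcoxon(fc, alternative="less", zero_method="wilcox", method=method)
    p = float(res.pvalue)
    return ResponseCall(
        subject_id=subject_id,
        delta_score=float(fc.mean()),
        statistic=float(res.statistic),
        p=p,
        responder=p < alpha,
        n_genes=fc.size,
        rule=rule,
    )


def paired_log2_fold_changes(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    signature: SignatureDefinition | None = None,
) -> pd.DataFrame:
    """Per-subject per-gene log2 fold changes from paired expression profiles.

    Each subject must contribute exactly one control and one treated sample;
    values are log2-scale, so the fold change is treated minus control.
    Restricted to signature genes when a signature is given. Returns a
    genes x subjects DataFrame.
    """
    meta = metadata.set_index("sample_id")
    cols = {}
    for subject, block in meta.groupby("subject_id", sort=True):
        conds = block["condition"]
        ctrl = block.index[conds == "control"]
        trt = block.index[conds == "treated"]
        if len(ctrl) != 1 or len(trt) != 1:
            raise ValueError(
                f"subject {subject!r} needs exactly one control and one treated sample, "
                f"got {len(ctrl)}/{len(trt)}"
            )
        cols[str(subject)] = matrix.data[trt[0]] - matrix.data[ctrl[0]]
    fc = pd.DataFrame(cols)
    if signature is not None:
        present = [g for g in signature.genes if g in fc.index]
        fc = fc.loc[present]
    return fc


def count_responders(calls) -> tuple[int, int, float]:
    """Summarize responder calls as (n_responders, n_total, fraction)."""
    calls = list(calls)
    if not calls:
        raise ValueError("no response calls to count")
    n_resp = sum(1 for c in calls if c.responder)
    return n_resp, len(calls), n_resp / len(calls)
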