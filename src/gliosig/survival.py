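"""Kaplan-Meier estimation, Mantel-Cox log-rank, and ROC/AUC evaluation.

Prognostic evaluation stratifies samples into high/low signature-score
groups and compares their censored survival with the two-sided log-rank
test; diagnostic evaluation treats the score as a classifier of
case-vs-control labels and summarizes it with the ROC curve and its AUC
(computed through the rank / Mann-Whitney U relation, which handles score
ties via mid-ranks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "KmCurve",
    "LogrankResult",
    "RocResult",
    "km_estimate",
    "logrank_test",
    "roc_auc",
]


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival estimate on the observed event-time grid."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    median: float  # NaN when the curve never crosses 0.5 ("not reached")

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    ``times`` are follow-up durations (months, >= 0); ``events`` are 1 for an
    observed event and 0 for right-censoring. Samples censored exactly at an
    event time count as at risk for that time (standard convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    if not np.isin(events, (0.0, 1.0)).all():
        raise ValueError("events must be 0 or 1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)  # inf when not reached
    return KmCurve(
        timeline=timeline,
        survival=survival,
        at_risk=at_risk,
        censor_times=np.sort(times[events == 0.0]),
        median=median if np.isfinite(median) else float("nan"),
    )


@dataclass(frozen=True)
class LogrankResult:
    """Mantel-Cox two-group log-rank test."""

    statistic: float  # chi-square, 1 df
    p: float  # two-sided
    observed: dict[str, float]
    expected: dict[str, float]


def logrank_test(times, events, group_labels) -> LogrankResult:
    """Two-group Mantel-Cox log-rank test on right-censored survival data.

    At each distinct event time the observed events in group 1 are compared
    with their hypergeometric expectation given the risk sets; the statistic
    is (sum O - sum E)^2 / sum V, referred to chi-square with 1 df (two-sided
    by construction).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    groups = np.asarray(group_labels)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    g1 = groups == labels[0]
    if g1.sum() == 0 or (~g1).sum() == 0:
        raise ValueError("both groups must be non-empty")

    event_times = np.unique(times[events == 1.0])
    o_minus_e = 0.0
    var = 0.0
    obs = {str(labels[0]): 0.0, str(labels[1]): 0.0}
    exp = {str(labels[0]): 0.0, str(labels[1]): 0.0}
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1.0)).sum()
        d1 = ((times == t) & (events == 1.0) & g1).sum()
        e1 = d * n1 / n
        obs[str(labels[0])] += float(d1)
        obs[str(labels[1])] += float(d - d1)
        exp[str(labels[0])] += float(e1)
        exp[str(labels[1])] += float(d - e1)
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogrankResult(statistic=0.0, p=1.0, observed=obs, expected=exp)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(statistic=float(chi2), p=p, observed=obs, expected=exp)


@dataclass(frozen=True)
class RocResult:
    """ROC curve and area under it for a score against binary labels."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores, binary_labels, positive_label=1) -> RocResult:
    """ROC curve and AUC of ``scores`` for predicting ``binary_labels``.

    AUC is computed from mid-ranks via the Mann-Whitney U relation
    ``AUC = U_pos / (n_pos * n_neg)``, which equals the trapezoidal area
    under the empirical curve with ties handled symmetrically. The curve
    enumerates all distinct score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels)
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u_pos = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u_pos / (n_pos * n_neg)
    fpr, tpr, thresholds = _sk_roc_curve(pos.astype(int), scores)
    return RocResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=float(auc),
    )
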