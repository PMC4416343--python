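"""Automated class-effect determination from member-drug log-PRRs.

For an eligible (drug class, adverse event) pair — a class with at least
four member drugs, every one of which co-occurs with the event in the
literature — the log-transformed member PRRs are partitioned into two
groups by one-dimensional two-means clustering, and the group means are
compared with Welch's t-test.  A class effect is concluded when the values
are too similar to form two clusters, or when the two cluster means do not
differ significantly (two-sided p > alpha, default 0.05): in both cases all
member drugs contribute comparably to the class signal.  Otherwise the
signal is driven by a subset of members and the pair is called
heterogeneous.

The 1-D clustering is solved exactly rather than with randomly-initialized
Lloyd iterations: values are sorted and every contiguous split with both
sides holding at least ``min_cluster_size`` values is scored by total
within-cluster sum of squares (the optimal 1-D two-means partition is
always contiguous in sorted order).  The minimum cluster size of 2 keeps
Welch's test well defined.  A seeded Lloyd-style mode is provided for
comparison with conventional k-means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .signals import SignalRecord

__all__ = [
    "ClassEffectResult",
    "eligible_pairs",
    "split_two",
    "lloyd_split",
    "welch_test",
    "classify_pair",
    "class_effect_scan",
    "VERDICT_SINGLE",
    "VERDICT_HOMOGENEOUS",
    "VERDICT_HETEROGENEOUS",
]

VERDICT_SINGLE = "class_effect_single_cluster"
VERDICT_HOMOGENEOUS = "class_effect_homogeneous"
VERDICT_HETEROGENEOUS = "heterogeneous"


@dataclass
class ClassEffectResult:
    """Verdict, clustering and test statistics for one (class, ADE) pair."""

    class_id: str
    ade_id: str
    member_log_prrs: dict[str, float]
    n_clusters: int
    partition: tuple[tuple[str, ...], tuple[str, ...]]
    cluster_means: tuple[float, ...]
    t_stat: float | None
    dof: float | None
    p_value: float | None
    verdict: str
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def is_class_effect(self) -> bool:
        return self.verdict in (VERDICT_SINGLE, VERDICT_HOMOGENEOUS)


def eligible_pairs(
    class_members: Mapping[str, set[str]],
    drug_level_records: Iterable[SignalRecord],
) -> list[tuple[str, str]]:
    """(class, ADE) pairs where every member drug has co-occurrence evidence.

    Pairs where some member never co-occurs with the event are excluded:
    absence of evidence cannot be distinguished from evidence of absence,
    so no verdict about the whole class is possible.  Class-size filtering
    (>= 4 members) is assumed to have been applied to ``class_members``.
    """
    by_ade: dict[str, set[str]] = {}
    for rec in drug_level_records:
        by_ade.setdefault(rec.col_id, set()).add(rec.row_id)
    out: list[tuple[str, str]] = []
    for cls in sorted(class_members):
        members = class_members[cls]
        for ade in sorted(by_ade):
            if members <= by_ade[ade]:
                out.append((cls, ade))
    return out


def split_two(
    values: Sequence[float], min_cluster_size: int = 2
) -> tuple[int, tuple[tuple[int, ...], tuple[int, ...]]]:
    """Deterministic optimal 1-D two-means split with a minimum group size.

    Returns ``(n_clusters, (low_indices, high_indices))`` where indices
    refer to the input order and the first group holds the smaller values.
    Fewer than two distinct values, or too few values to form two groups of
    ``min_cluster_size``, yield a single cluster (empty second group).
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    all_ix = tuple(range(n))
    if len(np.unique(vals)) < 2 or n < 2 * min_cluster_size:
        return 1, (all_ix, ())
    order = np.argsort(vals, kind="stable")
    s = vals[order]
    best_ss = np.inf
    best_i = None
    for i in range(min_cluster_size, n - min_cluster_size + 1):
        left, right = s[:i], s[i:]
        ss = np.sum((left - left.mean()) ** 2) + np.sum((right - right.mean()) ** 2)
        if ss < best_ss - 1e-15:
            best_ss = ss
            best_i = i
    low = tuple(sorted(int(k) for k in order[:best_i]))
    high = tuple(sorted(int(k) for k in order[best_i:]))
    return 2, (low, high)


def lloyd_split(
    values: Sequence[float], seed: int = 0, n_init: int = 10
) -> tuple[int, tuple[tuple[int, ...], tuple[int, ...]]]:
    """Conventional randomly-initialized k-means (k = 2) on scalar values.

    Provided for comparison with the deterministic :func:`split_two`; may
    return clusters of size 1, and with few restarts may miss the optimum.
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if len(np.unique(vals)) < 2:
        return 1, (tuple(range(n)), ())
    rng = np.random.default_rng(seed)
    best_ss, best_labels = np.inf, None
    for _ in range(n_init):
        centers = rng.choice(np.unique(vals), size=2, replace=False)
        for _ in range(100):
            labels = np.abs(vals[:, None] - centers[None, :]).argmin(axis=1)
            new = np.array(
                [vals[labels == k].mean() if np.any(labels == k) else centers[k]
                 for k in range(2)]
            )
            if np.allclose(new, centers):
                break
            centers = new
        ss = sum(
            np.sum((vals[labels == k] - vals[labels == k].mean()) ** 2)
            for k in range(2)
            if np.any(labels == k)
        )
        if ss < best_ss:
            best_ss, best_labels = ss, labels
    means = [vals[best_labels == k].mean() for k in (0, 1)]
    lo = 0 if means[0] <= means[1] else 1
    low = tuple(int(i) for i in np.flatnonzero(best_labels == lo))
    high = tuple(int(i) for i in np.flatnonzero(best_labels != lo))
    if not low or not high:
        return 1, (tuple(range(n)), ())
    return 2, (low, high)


def welch_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Returns (t statistic, Welch-Satterthwaite degrees of freedom, p-value).
    When both sample variances are zero the test degenerates: p = 1 if the
    means are equal, p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values for Welch's test")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        equal = a.mean() == b.mean()
        return (0.0 if equal else np.inf), float("nan"), (1.0 if equal else 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def classify_pair(
    class_id: str,
    ade_id: str,
    member_log_prrs: Mapping[str, float],
    alpha: float = 0.05,
    min_cluster_size: int = 2,
) -> ClassEffectResult:
    """Apply the cluster-then-test decision rule to one (class, ADE) pair."""
    members = list(member_log_prrs)
    vals = [member_log_prrs[m] for m in members]
    n_clusters, (lo_ix, hi_ix) = split_two(vals, min_cluster_size=min_cluster_size)
    degenerate = n_clusters == 1 and len(set(vals)) >= 2
    lo = tuple(members[i] for i in lo_ix)
    hi = tuple(members[i] for i in hi_ix)
    if n_clusters == 1:
        return ClassEffectResult(
            class_id=class_id,
            ade_id=ade_id,
            member_log_prrs=dict(member_log_prrs),
            n_clusters=1,
            partition=(lo, hi),
            cluster_means=(float(np.mean(vals)),),
            t_stat=None,
            dof=None,
            p_value=None,
            verdict=VERDICT_SINGLE,
            alpha=alpha,
            degenerate=degenerate,
        )
    lo_vals = [member_log_prrs[m] for m in lo]
    hi_vals = [member_log_prrs[m] for m in hi]
    t, dof, p = welch_test(lo_vals, hi_vals)
    verdict = VERDICT_HOMOGENEOUS if p > alpha else VERDICT_HETEROGENEOUS
    return ClassEffectResult(
        class_id=class_id,
        ade_id=ade_id,
        member_log_prrs=dict(member_log_prrs),
        n_clusters=2,
        partition=(lo, hi),
        cluster_means=(float(np.mean(lo_vals)), float(np.mean(hi_vals))),
        t_stat=t,
        dof=dof,
        p_value=p,
        verdict=verdict,
        alpha=alpha,
    )


def class_effect_scan(
    eligible: Sequence[tuple[str, str]],
    drug_signals: Sequence[SignalRecord],
    class_members: Mapping[str, set[str]],
    class_signals: Sequence[SignalRecord] = (),
    alpha: float = 0.05,
) -> list[ClassEffectResult]:
    """Classify every eligible (class, ADE) pair.

    ``drug_signals`` are member-drug-level records against the same ADE
    column unit as the pairs (term or class resolution).  One result per
    eligible pair, in input order.
    """
    by_pair = {(r.row_id, r.col_id): r for r in drug_signals}
    results: list[ClassEffectResult] = []
    for cls, ade in eligible:
        member_log_prrs = {
            m: by_pair[(m, ade)].log_prr for m in sorted(class_members[cls])
        }
        results.append(classify_pair(cls, ade, member_log_prrs, alpha=alpha))
    return results
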