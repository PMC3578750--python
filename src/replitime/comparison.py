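"""Replication-timing comparisons between promoter groups.

Implements the percentile bootstrap of the group mean (resampling depth
10^4, interval endpoints at the alpha and 1-alpha empirical quantiles of
the bootstrap means, alpha = 0.025 per tail so the default interval is
95%), an importance-weighted bootstrap in which each promoter is drawn with
probability inversely proportional to the size of its ON/OFF activity
class (so both classes contribute equal total weight, removing the
transcription-composition difference between groups), and the two-sided
Wilcoxon rank-sum test.

The unweighted bootstrap is the weighted bootstrap with uniform weights and
shares its sampling path, so the two are stream-identical under the same
seed.  Raw p-values are reported without multiple-testing correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import EmptyGroupError

__all__ = [
    "BootstrapResult",
    "GroupComparison",
    "bootstrap_ci_mean",
    "class_importance_weights",
    "weighted_bootstrap_ci_mean",
    "wilcoxon_ranksum",
    "exact_ranksum_p",
    "compare_timing_groups",
]


@dataclass
class BootstrapResult:
    """Percentile bootstrap interval for a group mean."""

    mean_estimate: float
    ci_low: float
    ci_high: float
    n_resamples: int
    alpha: float
    weighted: bool
    seed: int
    bootstrap_means: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "mean_estimate": self.mean_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_resamples": self.n_resamples,
            "alpha": self.alpha,
            "weighted": self.weighted,
            "seed": self.seed,
        }


@dataclass
class GroupComparison:
    """Two-group replication-timing comparison."""

    group_labels: tuple[str, str]
    n_per_group: tuple[int, int]
    five_number_summaries: dict[str, tuple[float, float, float, float, float]]
    wilcoxon_p: float
    bootstrap: dict[str, BootstrapResult]
    ci_overlap: bool

    def to_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "n_per_group": list(self.n_per_group),
            "five_number_summaries": {
                k: list(v) for k, v in self.five_number_summaries.items()
            },
            "wilcoxon_p": self.wilcoxon_p,
            "bootstrap": {k: v.to_dict() for k, v in self.bootstrap.items()},
            "ci_overlap": self.ci_overlap,
        }


def _resample_means(
    rng: np.random.Generator,
    values: np.ndarray,
    n_resamples: int,
    weights: np.ndarray,
    block: int = 200,
) -> np.ndarray:
    """Means of with-replacement resamples drawn by inverse-CDF sampling.

    The same sampling path serves weighted and unweighted resampling
    (uniform weights), so equal seeds give equal streams.  Resamples are
    drawn in blocks to bound memory.
    """
    n = len(values)
    cum = np.cumsum(weights)
    cum[-1] = 1.0  # guard against rounding drift
    means = np.empty(n_resamples)
    done = 0
    while done < n_resamples:
        b = min(block, n_resamples - done)
        u = rng.random((b, n))
        idx = np.searchsorted(cum, u, side="right")
        np.clip(idx, 0, n - 1, out=idx)
        means[done : done + b] = values[idx].mean(axis=1)
        done += b
    return means


def bootstrap_ci_mean(
    values,
    n_resamples: int = 10_000,
    alpha: float = 0.025,
    seed: int = 0,
    keep_means: bool = True,
) -> BootstrapResult:
    """Percentile bootstrap CI for the mean.

    Draws ``n_resamples`` resamples of size n with replacement and returns
    the (alpha, 1 - alpha) empirical quantiles of their means (linear
    interpolation between order statistics), i.e. a 95% interval at the
    default alpha = 0.025 per tail.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise EmptyGroupError("cannot bootstrap an empty sample")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    weights = np.full(len(x), 1.0 / len(x))
    rng = np.random.default_rng(seed)
    means = _resample_means(rng, x, n_resamples, weights)
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return BootstrapResult(
        mean_estimate=float(x.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
        alpha=alpha,
        weighted=False,
        seed=seed,
        bootstrap_means=means if keep_means else None,
    )


def class_importance_weights(statuses) -> np.ndarray:
    """Per-promoter importance weights inversely proportional to class size.

    With k represented classes, a promoter in a class of size m gets weight
    1 / (k * m): weights sum to 1 and each class carries equal total
    weight, equalizing ON/OFF composition in expectation.
    """
    statuses = np.asarray(statuses)
    if len(statuses) == 0:
        raise EmptyGroupError("no promoters to weight")
    labels, inverse, counts = np.unique(
        statuses, return_inverse=True, return_counts=True
    )
    k = len(labels)
    return 1.0 / (k * counts[inverse])


def weighted_bootstrap_ci_mean(
    values,
    statuses,
    n_resamples: int = 10_000,
    alpha: float = 0.025,
    seed: int = 0,
    keep_means: bool = True,
    weights=None,
) -> BootstrapResult:
    """Importance-weighted percentile bootstrap CI for the mean.

    Identical to :func:`bootstrap_ci_mean` except that promoter i is drawn
    with probability proportional to 1 / |activity class of i|, with class
    sizes taken within the sample (within-group equalization).  Pass
    explicit ``weights`` (summing to 1) to weight against an external
    reference composition instead, e.g. class weights computed on the
    pooled promoter set.
    """
    x = np.asarray(values, dtype=float)
    statuses = np.asarray(statuses)
    if len(x) != len(statuses):
        raise ValueError(
            f"values ({len(x)}) and statuses ({len(statuses)}) differ in length"
        )
    if len(x) == 0:
        raise EmptyGroupError("cannot bootstrap an empty sample")
    if weights is None:
        weights = class_importance_weights(statuses)
    else:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(x):
            raise ValueError("weights must align with values")
        weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    means = _resample_means(rng, x, n_resamples, weights)
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return BootstrapResult(
        mean_estimate=float(x.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
        alpha=alpha,
        weighted=True,
        seed=seed,
        bootstrap_means=means if keep_means else None,
    )


def wilcoxon_ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration of the null distribution when the pooled sample
    has at most 12 observations and no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise EmptyGroupError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    small = len(pooled) <= 12 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if small else "asymptotic"
    res = mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def exact_ranksum_p(x, y) -> float:
    """Exact two-sided rank-sum p-value by full enumeration (no ties).

    Enumerates all C(n, m) assignments of the pooled ranks to the first
    sample and doubles the smaller tail probability of the observed rank
    sum (capped at 1).  Reference implementation used to validate
    :func:`wilcoxon_ranksum`; feasible only for small pooled samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) != len(pooled):
        raise ValueError("exact enumeration requires untied values")
    ranks = pooled.argsort().argsort() + 1
    m = len(x)
    w_obs = int(ranks[:m].sum())
    sums = [sum(c) for c in itertools.combinations(ranks.tolist(), m)]
    total = len(sums)
    p_le = sum(1 for s in sums if s <= w_obs) / total
    p_ge = sum(1 for s in sums if s >= w_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def compare_timing_groups(
    promoters: pd.DataFrame,
    membership: pd.Series,
    statuses: pd.Series | None = None,
    n_resamples: int = 10_000,
    alpha: float = 0.025,
    seed: int = 0,
    keep_means: bool = False,
) -> GroupComparison:
    """Compare replication timing between two promoter groups.

    Parameters
    ----------
    promoters
        Promoter table with replication_timing and discarded columns
        (discarded promoters are excluded).
    membership
        promoter_id -> group label (exactly two labels).
    statuses
        Optional promoter_id -> ON/OFF; when given, the bootstrap is
        importance-weighted within each group so both activity classes
        contribute equal total weight.

    Returns the per-group five-number summaries, the two-sided Wilcoxon
    rank-sum p-value, per-group bootstrap CIs and whether the two
    percentile intervals overlap.  Per-group resampling streams are derived
    from ``seed`` via a seed sequence.
    """
    kept = promoters[~promoters["discarded"]]
    timing = kept.set_index("promoter_id")["replication_timing"]
    labels = sorted(pd.unique(membership.dropna()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {labels}")
    membership = membership.reindex(timing.index).dropna()
    for label in labels:
        if int((membership == label).sum()) == 0:
            raise EmptyGroupError(
                f"group {label!r} has no promoters after filtering"
            )
    child_seeds = np.random.SeedSequence(seed).generate_state(2)

    summaries: dict[str, tuple] = {}
    boots: dict[str, BootstrapResult] = {}
    group_values = {}
    for label, child in zip(labels, child_seeds):
        ids = membership.index[membership == label]
        vals = timing.loc[ids].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise EmptyGroupError(
                f"group {label!r} has no promoters after filtering"
            )
        group_values[label] = vals
        summaries[label] = tuple(
            float(q) for q in np.percentile(vals, [0, 25, 50, 75, 100])
        )
        if statuses is not None:
            st = statuses.reindex(ids).to_numpy()
            boots[label] = weighted_bootstrap_ci_mean(
                vals,
                st,
                n_resamples=n_resamples,
                alpha=alpha,
                seed=int(child),
                keep_means=keep_means,
            )
        else:
            boots[label] = bootstrap_ci_mean(
                vals,
                n_resamples=n_resamples,
                alpha=alpha,
                seed=int(child),
                keep_means=keep_means,
            )
    a, b = labels
    p = wilcoxon_ranksum(group_values[a], group_values[b])
    overlap = (
        boots[a].ci_low <= boots[b].ci_high
        and boots[b].ci_low <= boots[a].ci_high
    )
    return GroupComparison(
        group_labels=(a, b),
        n_per_group=(len(group_values[a]), len(group_values[b])),
        five_number_summaries=summaries,
        wilcoxon_p=p,
        bootstrap=boots,
        ci_overlap=bool(overlap),
    )
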