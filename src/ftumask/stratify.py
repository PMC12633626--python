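"""Region stratification of instance features.

The case-study workflow: instances of one observation type (e.g. peritubular
capillaries) are assigned to region strata defined by another channel (e.g.
pathologist-annotated IFTA regions), and a quantitative feature is compared
across strata with summary statistics and a two-sided Wilcoxon rank-sum
(Mann-Whitney U) test.

Region membership is binary -- "inside" if the instance falls on a non-zero
region pixel, else "outside" -- under one of two rules:

``centroid``
    the instance's rounded centroid pixel is inside the region (default:
    cheap and unambiguous);
``majority``
    strictly more than half of the instance's pixels overlap the region.

A three-way split (e.g. cortical IFTA / cortical non-IFTA / extracortical) is
obtained by composing two binary assignments with
:func:`combine_region_labels`.

The rank-sum test uses midranks for ties.  With at most 20 observations per
stratum the null distribution of U is enumerated exactly over all
assignments of the pooled midranks; otherwise the normal approximation with
tie correction and continuity correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, erf, sqrt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DimensionError, InsufficientDataError
from .model import BitmaskChannel, FeatureTable, instances_in_channel

__all__ = [
    "assign_regions",
    "combine_region_labels",
    "compare_strata",
    "StrataComparison",
]

EXACT_MAX_N = 20  # per-group cutoff for exact enumeration


def assign_regions(
    instances: BitmaskChannel,
    regions: BitmaskChannel,
    *,
    rule: str = "centroid",
    table: Optional[FeatureTable] = None,
) -> pd.Series:
    """Label each instance "inside" or "outside" a region channel.

    Only zero vs non-zero matters in the region channel; its instance IDs are
    ignored.  When a feature table is supplied its IDs are checked to cover
    the instances present in the plane.
    """
    if instances.plane.shape != regions.plane.shape:
        raise DimensionError(
            f"instance plane {instances.plane.shape} != region plane "
            f"{regions.plane.shape}"
        )
    if rule not in ("centroid", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    ids = instances_in_channel(instances)
    if table is not None:
        missing = set(int(i) for i in ids) - set(int(i) for i in table.ids)
        if missing:
            raise InsufficientDataError(
                f"table ids do not cover instances {sorted(missing)}"
            )
    region = regions.plane > 0
    plane = instances.plane
    labels: dict[int, str] = {}
    from scipy import ndimage

    objects = ndimage.find_objects(plane)
    for i in ids:
        sl = objects[int(i) - 1]
        sub = plane[sl] == i
        if rule == "centroid":
            rr, cc = np.nonzero(sub)
            r = int(round(rr.mean() + sl[0].start))
            c = int(round(cc.mean() + sl[1].start))
            inside = bool(region[min(r, region.shape[0] - 1),
                                 min(c, region.shape[1] - 1)])
        else:  # majority
            overlap = int(np.count_nonzero(sub & region[sl]))
            inside = overlap * 2 > int(np.count_nonzero(sub))
        labels[int(i)] = "inside" if inside else "outside"
    return pd.Series(labels, name="region", dtype="object")


def combine_region_labels(
    inner: pd.Series, outer: pd.Series, names: tuple[str, str, str] = (
        "inner", "outer_only", "neither"
    )
) -> pd.Series:
    """Compose two binary inside/outside assignments into a three-way split.

    ``inner`` is the finer region (e.g. IFTA), ``outer`` the enclosing one
    (e.g. cortex).  Instances inside both get ``names[0]``; inside ``outer``
    only, ``names[1]``; otherwise ``names[2]``.
    """
    idx = inner.index
    out = pd.Series(names[2], index=idx, name="region", dtype="object")
    out[(outer.loc[idx] == "inside")] = names[1]
    out[(outer.loc[idx] == "inside") & (inner == "inside")] = names[0]
    return out


# ---------------------------------------------------------------------------
# Rank-sum comparison
# ---------------------------------------------------------------------------

@dataclass
class StrataComparison:
    """Summary of a two-stratum feature comparison."""

    strata: list[str]
    summaries: dict[str, dict[str, float]]
    u_statistic: Optional[float]          # U of the first stratum
    p_value: Optional[float]
    method: Optional[str]                 # "exact" or "normal"
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_counts: dict[str, list[int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "strata": self.strata,
            "summaries": self.summaries,
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "method": self.method,
            "bin_edges": [float(b) for b in self.bin_edges],
            "bin_counts": self.bin_counts,
        }


_ENUM_BUDGET = 200_000  # max assignments enumerated brute-force for tied pools


def _rank_sum_counts(n: int, k: int) -> np.ndarray:
    """Count k-subsets of ranks 1..n by rank sum (generating-function DP)."""
    max_sum = sum(range(n - k + 1, n + 1))
    dp = np.zeros((k + 1, max_sum + 1), dtype=object)
    dp[0, 0] = 1
    for i in range(1, n + 1):
        for kk in range(min(k, i), 0, -1):
            dp[kk, i:] = dp[kk, i:] + dp[kk - 1, : max_sum + 1 - i]
    return dp[k]


def _exact_ranksum_p(ranks1: np.ndarray, pooled: np.ndarray, n1: int) -> Optional[float]:
    """Two-sided exact p over all assignments of the pooled midranks.

    p = P(min(U1, U2) <= observed min(U1, U2)) under the permutation null;
    ties are handled symmetrically through midranks, so identical samples
    give p = 1.  Untied pools use a rank-sum count recursion; tied pools are
    enumerated brute-force when small enough, otherwise ``None`` is returned
    and the caller falls back to the normal approximation.
    """
    n = len(pooled)
    n2 = n - n1
    u_obs1 = float(ranks1.sum()) - n1 * (n1 + 1) / 2
    m_obs = min(u_obs1, n1 * n2 - u_obs1)
    eps = 1e-9
    if len(np.unique(pooled)) == n:  # no ties: ranks are exactly 1..n
        counts = _rank_sum_counts(n, n1)
        base = n1 * (n1 + 1) // 2
        num = sum(
            int(c)
            for s, c in enumerate(counts)
            if c and min(s - base, n1 * n2 - (s - base)) <= m_obs + eps
        )
        return num / comb(n, n1)
    if comb(n, n1) <= _ENUM_BUDGET:
        count = 0
        for idx in combinations(range(n), n1):
            u1 = float(pooled[list(idx)].sum()) - n1 * (n1 + 1) / 2
            if min(u1, n1 * n2 - u1) <= m_obs + eps:
                count += 1
        return count / comb(n, n1)
    return None


def _normal_ranksum_p(u1: float, pooled: np.ndarray, n1: int) -> float:
    """Normal approximation with midrank tie correction and continuity 0.5."""
    n = len(pooled)
    n2 = n - n1
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(u1 - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    return 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))


def compare_strata(
    values: Sequence[float],
    labels: Sequence[str],
    bins: int = 10,
) -> StrataComparison:
    """Compare a feature's distribution across strata.

    Per-stratum n, median and IQR are always computed.  With exactly two
    strata a two-sided rank-sum test is run: exact enumeration when both
    groups have at most 20 observations, normal approximation with continuity
    and tie correction otherwise.  Histogram bin counts are computed on bins
    shared across strata.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if len(values) != len(labels):
        raise DimensionError("values and labels differ in length")
    strata = list(pd.unique(labels))
    if len(strata) < 1 or len(values) == 0:
        raise InsufficientDataError("no data to compare")
    groups = {s: values[labels == s] for s in strata}
    for s, g in groups.items():
        if len(g) == 0:
            raise InsufficientDataError(f"stratum {s!r} is empty")

    summaries = {}
    for s in strata:
        g = groups[s]
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        summaries[str(s)] = {
            "n": int(len(g)),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "iqr": float(q3 - q1),
        }

    u = p = method = None
    if len(strata) == 2:
        g1, g2 = groups[strata[0]], groups[strata[1]]
        n1, n2 = len(g1), len(g2)
        pooled = rankdata(np.concatenate([g1, g2]))  # midranks
        ranks1 = pooled[:n1]
        u = float(ranks1.sum()) - n1 * (n1 + 1) / 2
        p = method = None
        if max(n1, n2) <= EXACT_MAX_N:
            p = _exact_ranksum_p(ranks1, pooled, n1)
            method = "exact" if p is not None else None
        if p is None:
            p, method = _normal_ranksum_p(u, pooled, n1), "normal"
        p = min(p, 1.0)

    edges = np.histogram_bin_edges(values, bins=bins)
    counts = {
        str(s): np.histogram(groups[s], bins=edges)[0].tolist() for s in strata
    }
    return StrataComparison(
        strata=[str(s) for s in strata],
        summaries=summaries,
        u_statistic=u,
        p_value=p,
        method=method,
        bin_edges=edges,
        bin_counts=counts,
    )
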