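"""Protected-area effectiveness: labels and rank-based group comparisons.

A transect is *protected* when its first 2 km (closed interval) intersect
a protected-area polygon, and *urban* when its median population density
is at least 300 persons/km² (the urban-cluster threshold).  Group
comparisons use the Wilcoxon rank-sum test (normal approximation with tie
and continuity corrections, exact enumeration for small pooled samples)
and the Kruskal-Wallis test with Bonferroni-corrected pairwise posthocs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import LineString
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .aggregation_stats import lower_median, nearest_rank_percentile
from .transect_engine import Transect

logger = logging.getLogger(__name__)

PROTECTION_WINDOW_M = 2000.0
URBAN_THRESHOLD = 300.0

GROUP_NAMES = {
    (True, True): "urban_protected",
    (True, False): "urban_nonprotected",
    (False, True): "rural_protected",
    (False, False): "rural_nonprotected",
}


# ---------------------------------------------------------------- labelling

def assign_protection(
    transect: Transect,
    areas: list[BaseGeometry],
    window_m: float = PROTECTION_WINDOW_M,
    tree: STRtree | None = None,
) -> bool:
    """True iff the sub-segment [0, window_m] of the transect intersects any
    protected polygon (closed interval: boundary touching counts)."""
    sub = LineString([transect.point_at(0.0), transect.point_at(window_m)])
    if tree is None:
        candidates = range(len(areas))
    else:
        candidates = tree.query(sub)
    for i in candidates:
        geom = areas[i]
        if not geom.is_valid:
            logger.warning("skipping invalid protected polygon at index %d", i)
            continue
        if sub.intersects(geom):
            return True
    return False


def assign_protection_all(
    transects: list[Transect],
    areas: list[BaseGeometry],
    window_m: float = PROTECTION_WINDOW_M,
) -> np.ndarray:
    tree = STRtree(areas) if areas else None
    if tree is None:
        return np.zeros(len(transects), dtype=bool)
    return np.array(
        [assign_protection(t, areas, window_m, tree) for t in transects], dtype=bool
    )


def assign_urban(median_density: float, threshold: float = URBAN_THRESHOLD) -> bool | None:
    """Urban iff median transect density >= threshold; None when missing."""
    if median_density is None or not np.isfinite(median_density):
        return None
    if median_density < 0:
        raise ValueError("population density must be non-negative")
    return bool(median_density >= threshold)


def label_groups(
    protected: np.ndarray, urban: np.ndarray, transect_ids: np.ndarray
) -> pd.DataFrame:
    """Four-group labels; transects with a missing urban label are dropped."""
    rows = []
    for tid, p, u in zip(transect_ids, protected, urban):
        if u is None or (isinstance(u, float) and np.isnan(u)):
            continue
        rows.append(
            {
                "transect_id": tid,
                "protected": bool(p),
                "urban": bool(u),
                "group": GROUP_NAMES[(bool(u), bool(p))],
            }
        )
    return pd.DataFrame(rows, columns=["transect_id", "protected", "urban", "group"])


# ---------------------------------------------------------------- rank tests

@dataclass
class RankTestResult:
    test: str
    statistic: float  # Z for rank-sum, chi-square for Kruskal-Wallis
    p_value: float
    df: int | None = None
    group_medians: list[float] | None = None
    group_p75: list[float] | None = None
    posthoc: pd.DataFrame | None = None
    method: str = "asymptotic"


def _ranksum_moments(ranks_a: np.ndarray, pooled_ranks: np.ndarray, n1: int, n2: int):
    N = n1 + n2
    W = float(ranks_a.sum())
    mean = n1 * (N + 1) / 2.0
    _, counts = np.unique(pooled_ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    return W, mean, var


def rank_sum_test(
    sample_a,
    sample_b,
    method: str = "auto",
    continuity: bool = True,
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test.

    ``method='asymptotic'`` uses the normal approximation with tie
    correction and (optionally) a 0.5 continuity correction; ``'exact'``
    enumerates every assignment of the pooled values to the two groups
    (feasible for pooled n <= ~12).  ``'auto'`` picks exact for pooled
    n <= 10.  When all pooled values are identical the statistic is 0 and
    p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    W, mean, var = _ranksum_moments(ranks[:n1], ranks, n1, n2)
    meds = [lower_median(a), lower_median(b)]
    p75 = [nearest_rank_percentile(a, 0.75), nearest_rank_percentile(b, 0.75)]
    if var <= 0:  # all pooled values identical
        return RankTestResult("wilcoxon_rank_sum", 0.0, 1.0,
                              group_medians=meds, group_p75=p75, method="degenerate")
    N = n1 + n2
    if method == "auto":
        method = "exact" if N <= 10 else "asymptotic"
    if method == "exact":
        obs_dev = abs(W - mean)
        total = math.comb(N, n1)
        extreme = 0
        for idx in combinations(range(N), n1):
            w = ranks[list(idx)].sum()
            if abs(w - mean) >= obs_dev - 1e-12:
                extreme += 1
        return RankTestResult(
            "wilcoxon_rank_sum",
            statistic=(W - mean) / math.sqrt(var),
            p_value=extreme / total,
            group_medians=meds,
            group_p75=p75,
            method="exact",
        )
    shift = 0.0
    if continuity:
        shift = 0.5 * np.sign(W - mean)
    z = (W - mean - shift) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return RankTestResult(
        "wilcoxon_rank_sum", z, min(p, 1.0),
        group_medians=meds, group_p75=p75, method="asymptotic",
    )


def _kw_h(ranks: np.ndarray, sizes: list[int], tie_factor: float) -> float:
    """Tie-corrected Kruskal-Wallis H for pooled ranks split by ``sizes``."""
    N = len(ranks)
    start, h = 0, 0.0
    for n in sizes:
        h += ranks[start : start + n].sum() ** 2 / n
        start += n
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    return h / tie_factor if tie_factor > 0 else 0.0


def _kw_permutation_p(ranks: np.ndarray, sizes: list[int], tie_factor: float) -> float:
    """Exact p by enumerating all assignments of the pooled ranks to groups."""
    h_obs = _kw_h(ranks, sizes, tie_factor)
    hits = total = 0

    def recurse(avail: tuple[int, ...], gi: int, chosen: list[int]):
        nonlocal hits, total
        if gi == len(sizes) - 1:
            perm = chosen + list(avail)
            total += 1
            if _kw_h(ranks[perm], sizes, tie_factor) >= h_obs - 1e-12:
                hits += 1
            return
        for idx in combinations(range(len(avail)), sizes[gi]):
            picked = [avail[k] for k in idx]
            rest = tuple(a for k, a in enumerate(avail) if k not in idx)
            recurse(rest, gi + 1, chosen + picked)

    recurse(tuple(range(len(ranks))), 0, [])
    return hits / total


#: pooled sample size up to which the Kruskal-Wallis p-value is computed by
#: exhaustive permutation enumeration under method='auto'
KW_EXACT_MAX_N = 10


def kruskal_wallis_posthoc(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    alpha: float = 0.05,
    method: str = "auto",
) -> RankTestResult:
    """Kruskal-Wallis chi-square (tie corrected) over >=2 groups, followed by
    all pairwise rank-sum tests with Bonferroni-adjusted significance
    (alpha / number of pairs; 6 pairs for 4 groups).  Groups with n < 2 are
    dropped with a warning and the degrees of freedom reduced.  The p-value
    uses the chi-square approximation, or exhaustive permutation enumeration
    for pooled n <= 10 (``method='auto'``/``'exact'``)."""
    if isinstance(groups, dict):
        names = list(groups)
        samples = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        names = [f"group_{i}" for i in range(len(groups))]
        samples = [np.asarray(g, dtype=float) for g in groups]
    keep = [i for i, s in enumerate(samples) if len(s) >= 2]
    if len(keep) < len(samples):
        dropped = [names[i] for i in range(len(samples)) if i not in keep]
        logger.warning("dropping groups with n < 2: %s", dropped)
    names = [names[i] for i in keep]
    samples = [samples[i] for i in keep]
    if len(samples) < 2:
        raise ValueError("need at least 2 non-empty groups")
    df = len(samples) - 1
    pooled = np.concatenate(samples)
    if method == "auto":
        method = "exact" if len(pooled) <= KW_EXACT_MAX_N else "asymptotic"
    if np.all(pooled == pooled[0]):
        chi2, p = 0.0, 1.0
    elif method == "exact":
        ranks = sps.rankdata(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        N = len(pooled)
        tie_factor = 1 - ((counts**3 - counts).sum()) / (N**3 - N)
        sizes = [len(s) for s in samples]
        chi2 = _kw_h(ranks, sizes, tie_factor)
        p = _kw_permutation_p(ranks, sizes, tie_factor)
    else:
        chi2, p = sps.kruskal(*samples)
    pairs = []
    n_pairs = len(samples) * (len(samples) - 1) // 2
    for i, j in combinations(range(len(samples)), 2):
        r = rank_sum_test(samples[i], samples[j], method="asymptotic")
        pairs.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "z": r.statistic,
                "p_value": r.p_value,
                "significant": r.p_value < alpha / n_pairs,
            }
        )
    return RankTestResult(
        test="kruskal_wallis",
        statistic=float(chi2),
        p_value=float(p),
        df=df,
        group_medians=[lower_median(s) for s in samples],
        group_p75=[nearest_rank_percentile(s, 0.75) for s in samples],
        posthoc=pd.DataFrame(pairs),
    )
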