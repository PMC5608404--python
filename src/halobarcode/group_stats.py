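"""Intraspecific-distance extraction, Mann–Whitney comparison, and boxplot
summaries of habitat-stratified genetic distance distributions.

The comparison of interest is inland-only versus combined (inland plus
coastal) intraspecific K2P distances. The combined set contains the inland
samples, so the two distance vectors overlap; this mirrors the original
procedure and is reproduced verbatim, with a disjoint inland-vs-coastal
mode available for statistically cleaner contrasts. Pairwise distances are
not independent observations either — the test is reproduced as performed,
not endorsed as inference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

from .distance import DistanceMatrix

logger = logging.getLogger(__name__)

#: Largest pooled size for which the exact null distribution is enumerated.
EXACT_LIMIT = 16


def intraspecific_distances(
    matrix: DistanceMatrix,
    species_labels: dict[str, str],
    groups: dict[str, str] | None = None,
    subset_groups=None,
) -> np.ndarray:
    """All defined pairwise distances between conspecific samples.

    Restricted to samples whose habitat group is in ``subset_groups`` when
    given. Undefined entries are skipped with a logged count.
    """
    ids = matrix.sample_ids
    if subset_groups is not None:
        wanted = set(subset_groups)
        ids = [s for s in ids if groups is not None and groups[s] in wanted]
    if len(ids) < 2:
        raise ValueError("need at least 2 samples in the chosen subset")
    idx = {s: matrix.sample_ids.index(s) for s in ids}
    out = []
    skipped = 0
    for a, b in combinations(ids, 2):
        if species_labels[a] != species_labels[b]:
            continue
        d = matrix.values[idx[a], idx[b]]
        if math.isnan(d):
            skipped += 1
        else:
            out.append(d)
    if skipped:
        logger.info("intraspecific_distances: skipped %d undefined pairs", skipped)
    return np.asarray(out, dtype=float)


@dataclass
class MwResult:
    """Two-sided Mann–Whitney U result.

    ``U`` is the statistic for the first sample; ``U + U_other == n1 * n2``.
    ``method`` records whether the p-value came from exact enumeration of
    rank arrangements (small tie-free inputs) or from the tie-corrected
    normal approximation with a 0.5 continuity correction (the SPSS-style
    asymptotic two-sided p).
    """

    U: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_approx"
    z: float
    p_two_sided: float


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U: counts[u] over all C(n1+n2, n1) arrangements.

    Classic partition recurrence: c(n1, n2, u) = c(n1-1, n2, u-n2) +
    c(n1, n2-1, u).
    """
    dp: dict[tuple[int, int], np.ndarray] = {}

    def counts(i: int, j: int) -> np.ndarray:
        if (i, j) in dp:
            return dp[(i, j)]
        res = np.zeros(i * j + 1)
        if i == 0 or j == 0:
            res[0] = 1.0
        else:
            a = counts(i - 1, j)  # last pooled element from sample 1: U += j? no
            b = counts(i, j - 1)
            # If the largest pooled value belongs to sample 1 it beats all j
            # sample-2 values: U gains j. Otherwise U unchanged.
            res[j : j + len(a)] += a
            res[: len(b)] += b
        dp[(i, j)] = res
        return res

    return counts(n1, n2)


def mann_whitney(x, y) -> MwResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when n1 + n2 <= 16 and the pooled sample is tie-free;
    otherwise a normal approximation with tie-corrected variance and a 0.5
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2

    if n1 + n2 <= EXACT_LIMIT and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        u_lo = int(min(u1, n1 * n2 - u1))
        if 2 * u_lo == n1 * n2:  # statistic at the exact center: tails overlap
            p = 1.0
        else:
            p = (counts[: u_lo + 1].sum() + counts[n1 * n2 - u_lo :].sum()) / total
        p = min(1.0, float(p))
        return MwResult(U=float(u1), n1=n1, n2=n2, method="exact", z=math.nan, p_two_sided=p)

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:  # all values identical
        return MwResult(U=float(u1), n1=n1, n2=n2, method="normal_approx", z=0.0, p_two_sided=1.0)
    cc = 0.5 if abs(u1 - mean_u) > 0 else 0.0
    z = (u1 - mean_u - math.copysign(cc, u1 - mean_u)) / math.sqrt(var_u)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return MwResult(U=float(u1), n1=n1, n2=n2, method="normal_approx", z=float(z), p_two_sided=p)


@dataclass
class BoxplotStats:
    """Five-number summary with Tukey 1.5*IQR outlier fences."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def boxplot_stats(values) -> BoxplotStats:
    """Tukey boxplot summary (linear-interpolation quartiles).

    Whiskers extend to the most extreme data points inside the
    q1 - 1.5*IQR and q3 + 1.5*IQR fences; points beyond are outliers.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("boxplot_stats requires a non-empty vector")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotStats(
        minimum=float(v[0]),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(v[-1]),
        whisker_low=float(inside[0]),
        whisker_high=float(inside[-1]),
        outliers=outliers,
    )
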