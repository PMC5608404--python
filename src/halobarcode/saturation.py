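"""Sampling-sufficiency analysis: theta resampling across subset sizes.

For one species, theta of a subset is the mean pairwise K2P distance among
its members. For every subset size n from 2 to N (the species' full sample
size), a fixed number of random subsets (default 20) are drawn without
replacement; the per-size trend statistic is the MAXIMUM of the replicate
thetas (each replicate's theta is itself an average, so this is the
"maximum average value" trend line). The species' minimum sufficient sample
size is the smallest n from which the trend stays at or below the upper
limit of the Student-t confidence interval (default confidence 99.99%) of
the full-sample mean pairwise distance — a stability rule, not a first
crossing, because trend lines fluctuate.

The confidence interval treats the individual pairwise distances as
independent observations; they are not (each individual contributes to
N - 1 pairs), and the interval is reproduced as the procedure defines it,
not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .distance import DistanceMatrix
from .errors import UndefinedDistanceError

#: Sentinel for a curve whose trend never stabilizes below the CI before N.
NOT_REACHED = None

RULES = ("stable", "first")


def theta(matrix: DistanceMatrix, subset) -> float:
    """Mean pairwise distance among the subset's C(n, 2) pairs."""
    subset = list(subset)
    if len(subset) < 2:
        raise ValueError("theta requires a subset of at least 2 samples")
    idx = [matrix.sample_ids.index(s) for s in subset]
    vals = []
    for a, b in combinations(range(len(idx)), 2):
        d = matrix.values[idx[a], idx[b]]
        if math.isnan(d):
            raise UndefinedDistanceError(
                f"undefined distance between {subset[a]!r} and {subset[b]!r}"
            )
        vals.append(d)
    return float(np.mean(vals))


def mean_ci(distances, confidence: float = 0.9999) -> tuple[float, float]:
    """Student-t confidence interval for the mean of ``distances``.

    mean +/- t_{(1+c)/2, m-1} * sd / sqrt(m) over the m values, treated as
    independent. Zero variance yields the degenerate interval (mean, mean).
    """
    v = np.asarray(distances, dtype=float)
    if v.size < 2:
        raise ValueError("mean_ci requires at least 2 values")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    m = v.size
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        return (mean, mean)
    half = stats.t.ppf((1 + confidence) / 2, m - 1) * sd / math.sqrt(m)
    return (mean - half, mean + half)


@dataclass
class SaturationCurve:
    """Replicate thetas, trend, and the CI verdict for one species."""

    species: str
    N: int
    ns: list[int]  # subset sizes 2..N
    replicate_thetas: list[np.ndarray]  # one array of length `replicates` per n
    mean_theta: np.ndarray
    trend_theta: np.ndarray  # max of the replicate thetas per n
    ci_low: float
    ci_high: float
    full_theta: float
    n_min: int | None = NOT_REACHED
    replicates: int = 20
    seed: int = 0
    rule: str = "stable"
    confidence: float = 0.9999

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "n": self.ns,
                "mean_theta": self.mean_theta,
                "trend_theta": self.trend_theta,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_min": -1 if self.n_min is NOT_REACHED else self.n_min,
                "replicate_thetas": [
                    ";".join("%.12g" % t for t in reps)
                    for reps in self.replicate_thetas
                ],
            }
        )


def _pairwise_vector(matrix: DistanceMatrix, ids) -> np.ndarray:
    idx = [matrix.sample_ids.index(s) for s in ids]
    sub = matrix.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    vals = sub[iu]
    if np.isnan(vals).any():
        bad = [(ids[i], ids[j]) for i, j in zip(*iu) if math.isnan(sub[i, j])]
        raise UndefinedDistanceError(f"undefined distances among subset: {bad[:5]}")
    return vals


def saturation_curve(
    matrix: DistanceMatrix,
    species_samples,
    species: str = "",
    replicates: int = 20,
    seed: int = 0,
    confidence: float = 0.9999,
    rule: str = "stable",
) -> SaturationCurve:
    """Theta-resampling curve for one species' samples.

    For each n in 2..N, draws ``replicates`` uniform random subsets without
    replacement and records their thetas, the replicate mean, and the trend
    (replicate maximum). Deterministic under (seed, input order). The
    confidence interval is computed once from the full set of pairwise
    distances and attached to every size.
    """
    ids = list(species_samples)
    big_n = len(ids)
    if big_n < 3:
        raise ValueError("saturation analysis needs at least 3 samples")
    pair_vals = _pairwise_vector(matrix, ids)
    full_theta = float(pair_vals.mean())
    ci_low, ci_high = mean_ci(pair_vals, confidence)

    # Precompute the submatrix once; thetas are means over index subsets.
    idx = [matrix.sample_ids.index(s) for s in ids]
    sub = matrix.values[np.ix_(idx, idx)]

    rng = np.random.default_rng(seed)
    ns = list(range(2, big_n + 1))
    rep_thetas: list[np.ndarray] = []
    for n in ns:
        thetas = np.empty(replicates)
        for r in range(replicates):
            pick = np.sort(rng.choice(big_n, size=n, replace=False))
            block = sub[np.ix_(pick, pick)]
            iu = np.triu_indices(n, k=1)
            thetas[r] = block[iu].mean()
        rep_thetas.append(thetas)
    # a mean of identical replicates (the n == N degeneracy) stays exact
    mean_theta = np.array(
        [t[0] if np.all(t == t[0]) else t.mean() for t in rep_thetas]
    )
    trend_theta = np.array([t.max() for t in rep_thetas])

    curve = SaturationCurve(
        species=species,
        N=big_n,
        ns=ns,
        replicate_thetas=rep_thetas,
        mean_theta=mean_theta,
        trend_theta=trend_theta,
        ci_low=ci_low,
        ci_high=ci_high,
        full_theta=full_theta,
        replicates=replicates,
        seed=seed,
        rule=rule,
        confidence=confidence,
    )
    curve.n_min = minimum_sample_size(curve, rule=rule)
    return curve


def minimum_sample_size(curve: SaturationCurve, rule: str = "stable") -> int | None:
    """Smallest sufficient subset size under the chosen rule.

    ``stable`` (default): smallest n such that the trend is <= the CI upper
    limit for ALL sizes >= n; NOT_REACHED when no such n below N exists.
    ``first``: the first size whose trend is <= the CI upper limit
    (sensitivity analysis only).
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    ns = curve.ns
    trend = curve.trend_theta
    ok = trend <= curve.ci_high
    if rule == "first":
        hits = np.nonzero(ok)[0]
        return int(ns[hits[0]]) if hits.size else NOT_REACHED
    # stable: suffix of all-ok sizes
    if not ok[-1]:
        return NOT_REACHED
    start = len(ok)
    for i in range(len(ok) - 1, -1, -1):
        if ok[i]:
            start = i
        else:
            break
    n_min = int(ns[start])
    return NOT_REACHED if n_min >= curve.N else n_min


def plot_saturation(curve: SaturationCurve, path) -> None:
    """Scatter of replicate thetas + trend line + CI upper limit + n_min arrow."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for n, reps in zip(curve.ns, curve.replicate_thetas):
        ax.scatter([n] * len(reps), reps, s=6, color="0.6", alpha=0.5)
    ax.plot(curve.ns, curve.trend_theta, color="tab:blue", label="trend (max of replicates)")
    ax.axhline(curve.ci_high, color="tab:orange", ls="--", label="CI upper limit")
    if curve.n_min is not NOT_REACHED:
        ax.annotate(
            f"n_min = {curve.n_min}",
            xy=(curve.n_min, curve.ci_high),
            xytext=(curve.n_min, curve.ci_high * 1.5 + 1e-4),
            arrowprops={"arrowstyle": "->", "color": "red"},
            color="red",
            fontsize=9,
        )
    ax.set_xlabel("sample size n")
    ax.set_ylabel("theta (mean pairwise K2P distance)")
    ax.set_title(curve.species)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
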