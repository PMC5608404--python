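"""Principal coordinate analysis (PCoA) of a genetic distance matrix.

Classical metric ordination: Gower double-centering of -1/2 * D∘D followed
by a symmetric eigendecomposition; coordinates are eigenvectors scaled by
the square roots of the positive eigenvalues. Negative eigenvalues (the
signature of a non-Euclidean distance) are dropped and reported, not
corrected — transparency over Lingoes/Cailliez adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .distance import DistanceMatrix
from .errors import UndefinedDistanceError


@dataclass
class PcoaResult:
    """Ordination coordinates with the eigenvalue bookkeeping.

    ``proportion_explained`` is each retained axis' percentage of the
    positive-eigenvalue sum (summing to 100 over retained axes). Axes are
    ordered by descending eigenvalue; each axis is sign-flipped so that its
    largest-magnitude loading is positive, making plots reproducible.
    """

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # descending, positive axes only
    proportion_explained: np.ndarray  # percent per retained axis
    negative_count: int
    negative_magnitude_sum: float

    def as_frame(self, species=None, groups=None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"axis_{k + 1}" for k in range(self.coordinates.shape[1])],
        )
        df.insert(0, "sample_id", self.sample_ids)
        if species is not None:
            df.insert(1, "species", [species[s] for s in self.sample_ids])
        if groups is not None:
            df.insert(
                2 if species is not None else 1,
                "group",
                [groups[s] for s in self.sample_ids],
            )
        return df


def pcoa(matrix: DistanceMatrix) -> PcoaResult:
    """Principal coordinates of a fully defined distance matrix.

    Refuses matrices with undefined entries, naming the offending pairs;
    the caller must filter or impute explicitly beforehand.
    """
    if matrix.n_undefined_pairs:
        pairs = matrix.undefined_pairs()
        shown = pairs[:5]
        more = f" (+{len(pairs) - 5} more)" if len(pairs) > 5 else ""
        raise UndefinedDistanceError(
            f"PCoA refuses undefined distances: {shown}{more}"
        )
    d = matrix.values
    n = d.shape[0]
    a = -0.5 * d * d
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = j @ a @ j
    b = 0.5 * (b + b.T)  # symmetrize against round-off
    eigvals, eigvecs = eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    scale = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0)
    tol = 1e-12 * scale  # |eigenvalue| below this is numerical zero
    pos = eigvals > tol
    neg = eigvals < -tol
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    for k in range(coords.shape[1]):  # sign convention
        i = int(np.argmax(np.abs(coords[:, k])))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    total = lam.sum()
    prop = 100.0 * lam / total if total > 0 else np.zeros_like(lam)
    return PcoaResult(
        sample_ids=list(matrix.sample_ids),
        coordinates=coords,
        eigenvalues=lam,
        proportion_explained=prop,
        negative_count=int(neg.sum()),
        negative_magnitude_sum=float(-eigvals[neg].sum()),
    )


def plot_pcoa(result: PcoaResult, groups: dict[str, str], path, title: str = "") -> None:
    """Scatter of the first two axes colored by habitat group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = result.coordinates
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"inland": "tab:blue", "coastal": "tab:red", "unassigned": "tab:gray"}
    for grp in sorted({groups[s] for s in result.sample_ids}):
        idx = [i for i, s in enumerate(result.sample_ids) if groups[s] == grp]
        x = xy[idx, 0] if xy.shape[1] >= 1 else np.zeros(len(idx))
        y = xy[idx, 1] if xy.shape[1] >= 2 else np.zeros(len(idx))
        ax.scatter(x, y, label=grp, s=18, alpha=0.8, color=colors.get(grp))
    pe = result.proportion_explained
    ax.set_xlabel(f"PCo1 ({pe[0]:.1f}%)" if len(pe) >= 1 else "PCo1")
    ax.set_ylabel(f"PCo2 ({pe[1]:.1f}%)" if len(pe) >= 2 else "PCo2")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
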