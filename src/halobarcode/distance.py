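"""Kimura 2-parameter (K2P) and p-distances over aligned sequence sets.

The K2P distance corrects observed divergence for multiple hits while
distinguishing transitions (A<->G, C<->T; proportion P) from transversions
(proportion Q):

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Columns where either residue is a gap, an N, or an IUPAC ambiguity code are
excluded from a comparison (full masking, matching the common MEGA setting;
ambiguities are never fractionally counted). When a log argument is <= 0 the
distance is undefined; undefined entries are carried as an explicit NaN
marker, never clamped to a large number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import AlignmentError, UndefinedComparisonError
from .sequence_io import AlignedSequenceSet

#: Marker for an undefined distance or an empty comparison.
UNDEFINED = float("nan")

MODELS = ("K2P", "p")
SITE_MODES = ("pairwise_deletion", "complete_deletion")

# Residue codes: A=0, C=1, G=2, T=3, anything else (gap/N/ambiguity) = 4.
# Purines (A, G) get even codes and pyrimidines (C, T) odd ones, so two
# differing valid residues are a transition iff their codes share parity.
_CODE = np.full(128, 4, dtype=np.int8)
for _c, _i in zip("ACGT", range(4)):
    _CODE[ord(_c)] = _i


def encode_rows(rows) -> np.ndarray:
    """Encode aligned rows as an (n, L) int8 matrix of residue codes."""
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return _CODE[arr].reshape(len(rows), -1)


@dataclass(frozen=True)
class SiteComparison:
    """Transition/transversion counts over the jointly valid columns."""

    transitions: int
    transversions: int
    valid_sites: int

    @property
    def P(self) -> float:
        if self.valid_sites == 0:
            raise UndefinedComparisonError("no jointly valid sites")
        return self.transitions / self.valid_sites

    @property
    def Q(self) -> float:
        if self.valid_sites == 0:
            raise UndefinedComparisonError("no jointly valid sites")
        return self.transversions / self.valid_sites


def compare_sites(row_a: str, row_b: str) -> SiteComparison:
    """Count transitions and transversions between two aligned rows.

    Columns with a gap, N, or ambiguity code in either row are excluded.
    """
    if len(row_a) != len(row_b):
        raise AlignmentError(
            f"rows differ in length: {len(row_a)} vs {len(row_b)}"
        )
    a, b = encode_rows([row_a, row_b])
    return _compare_encoded(a, b)


def _compare_encoded(a: np.ndarray, b: np.ndarray) -> SiteComparison:
    valid = (a < 4) & (b < 4)
    diff = valid & (a != b)
    ts = int(np.count_nonzero(diff & ((a & 1) == (b & 1))))
    tv = int(np.count_nonzero(diff)) - ts
    return SiteComparison(ts, tv, int(np.count_nonzero(valid)))


def k2p_distance(cmp: SiteComparison) -> float:
    """K2P distance from a site comparison; NaN when undefined.

    Undefined when there are no valid sites or a log argument is <= 0
    (saturation: observed divergence too large for the correction).
    """
    if cmp.valid_sites == 0:
        return UNDEFINED
    w1 = 1.0 - 2.0 * cmp.P - cmp.Q
    w2 = 1.0 - 2.0 * cmp.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return UNDEFINED
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def p_distance(cmp: SiteComparison) -> float:
    """Uncorrected proportion of differing valid sites; NaN when undefined."""
    if cmp.valid_sites == 0:
        return UNDEFINED
    return cmp.P + cmp.Q


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with explicit undefined entries (NaN)."""

    sample_ids: list[str]
    values: np.ndarray
    model: str = "K2P"
    site_mode: str = "pairwise_deletion"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise AlignmentError("matrix shape does not match sample ids")
        defined = ~np.isnan(v)
        if not np.array_equal(np.isnan(v), np.isnan(v.T)) or not np.allclose(
            np.nan_to_num(v), np.nan_to_num(v.T)
        ):
            raise AlignmentError("distance matrix is not symmetric")
        if not np.all(np.diag(v) == 0):
            raise AlignmentError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.any(v[defined] < 0):
                raise AlignmentError("negative distance entry")
        self.values = v

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self), k=1)
        return int(np.count_nonzero(np.isnan(self.values[iu])))

    def value(self, id_a: str, id_b: str) -> float:
        i = self.sample_ids.index(id_a)
        j = self.sample_ids.index(id_b)
        return float(self.values[i, j])

    def submatrix(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(
            list(sample_ids),
            self.values[np.ix_(idx, idx)].copy(),
            self.model,
            self.site_mode,
        )

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, j in zip(*np.triu_indices(len(self), k=1)):
            if math.isnan(self.values[i, j]):
                out.append((self.sample_ids[i], self.sample_ids[j]))
        return out


def pairwise_matrix(
    aset: AlignedSequenceSet,
    model: str = "K2P",
    site_mode: str = "pairwise_deletion",
) -> DistanceMatrix:
    """All pairwise distances for a sequence set.

    Under ``complete_deletion`` every column containing a gap/N/ambiguity in
    ANY row is removed once before all comparisons; ``pairwise_deletion``
    (the default, matching MEGA's distance default) masks per pair.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if site_mode not in SITE_MODES:
        raise ValueError(f"unknown site_mode {site_mode!r}")
    enc = encode_rows([s.row for s in aset.samples])
    if site_mode == "complete_deletion":
        keep = np.all(enc < 4, axis=0)
        enc = enc[:, keep]
    dist = k2p_distance if model == "K2P" else p_distance
    n = len(aset)
    values = np.zeros((n, n), dtype=float)
    for i, j in combinations(range(n), 2):
        d = dist(_compare_encoded(enc[i], enc[j]))
        values[i, j] = values[j, i] = d
    return DistanceMatrix(aset.sample_ids, values, model, site_mode)
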