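"""Best-close-match (BCM) species identification from a distance matrix.

TaxonDNA-style classification: each sequence is treated in turn as a query
against all other sequences. If the nearest neighbour is farther than the
distance threshold the query gets "no identification"; otherwise the query
is judged against the species of every neighbour tied at the minimum
distance — correct if they are all conspecific, ambiguous if conspecifics
and others are tied, incorrect otherwise. The per-locus summary reports the
four percentages (correct / ambiguous / incorrect / no id) that barcoding
studies tabulate.

The threshold may be supplied directly (the conventional 3% = 0.03) or
derived from the data as a percentile of all intraspecific pairwise
distances (the "pairwise summary" convention, default 95th percentile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .errors import UndefinedDistanceError

#: Absolute tie tolerance for "equal minimum distance": collapses
#: floating-point ties from identical sequences without merging
#: biologically distinct near-ties.
TIE_TOLERANCE = 1e-12

CATEGORIES = ("correct", "ambiguous", "incorrect", "no_id")


def intraspecific_threshold(
    matrix: DistanceMatrix,
    species_labels: dict[str, str],
    percentile: float = 95.0,
) -> float:
    """Percentile of all defined intraspecific pairwise distances.

    Uses linear interpolation between order statistics (numpy's default
    percentile rule). Undefined entries are excluded.
    """
    ids = matrix.sample_ids
    vals = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if species_labels[ids[i]] == species_labels[ids[j]]:
                d = matrix.values[i, j]
                if not math.isnan(d):
                    vals.append(d)
    if not vals:
        raise UndefinedDistanceError(
            "no defined intraspecific pairwise distances; "
            "supply a fixed threshold instead"
        )
    return float(np.percentile(vals, percentile))


@dataclass
class QueryResult:
    sample_id: str
    species: str
    category: str  # one of CATEGORIES or "uncomparable"
    closest_distance: float
    closest_species: tuple[str, ...]


@dataclass
class IdentificationSummary:
    """Per-query BCM outcomes plus the per-locus percentage summary."""

    locus: str
    threshold: float
    queries: list[QueryResult]
    n_uncomparable: int = 0
    percentages: dict[str, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [q.sample_id for q in self.queries],
                "species": [q.species for q in self.queries],
                "category": [q.category for q in self.queries],
                "closest_distance": [q.closest_distance for q in self.queries],
                "closest_species": [
                    ";".join(q.closest_species) for q in self.queries
                ],
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        row = {"locus": self.locus, "threshold": self.threshold}
        row.update({k: round(v, 2) for k, v in self.percentages.items()})
        row["n_queries"] = len(self.queries) - self.n_uncomparable
        row["n_uncomparable"] = self.n_uncomparable
        return pd.DataFrame([row])


def best_close_match(
    matrix: DistanceMatrix,
    species_labels: dict[str, str],
    threshold: float,
    locus: str = "locus",
    tie_tolerance: float = TIE_TOLERANCE,
) -> IdentificationSummary:
    """Classify every sample as a query against all others.

    The threshold comparison is inclusive (minimum distance <= threshold
    qualifies); self-matches are always excluded. Queries whose distances
    to every other sample are undefined are reported as ``uncomparable``
    and excluded from the percentages.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ids = matrix.sample_ids
    if len(ids) < 2:
        raise ValueError("best close match needs at least 2 samples")
    values = matrix.values
    queries: list[QueryResult] = []
    counts = dict.fromkeys(CATEGORIES, 0)
    n_uncomparable = 0
    for qi, qid in enumerate(ids):
        row = values[qi].copy()
        row[qi] = np.nan  # exclude self
        defined = ~np.isnan(row)
        if not defined.any():
            n_uncomparable += 1
            queries.append(
                QueryResult(qid, species_labels[qid], "uncomparable", math.nan, ())
            )
            continue
        m = float(np.nanmin(row))
        if m > threshold:
            category, closest = "no_id", ()
        else:
            tied = defined & (row <= m + tie_tolerance)
            closest_species = {species_labels[ids[j]] for j in np.nonzero(tied)[0]}
            closest = tuple(sorted(closest_species))
            own = species_labels[qid]
            if closest_species == {own}:
                category = "correct"
            elif own in closest_species:
                category = "ambiguous"
            else:
                category = "incorrect"
        counts[category] += 1
        queries.append(QueryResult(qid, species_labels[qid], category, m, closest))

    n_scored = len(ids) - n_uncomparable
    percentages = {
        cat: (100.0 * counts[cat] / n_scored if n_scored else math.nan)
        for cat in CATEGORIES
    }
    return IdentificationSummary(
        locus=locus,
        threshold=threshold,
        queries=queries,
        n_uncomparable=n_uncomparable,
        percentages=percentages,
    )
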