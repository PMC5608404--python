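import numpy as np
import pytest

from halobarcode import (
    AlignedSequenceSet,
    DistanceMatrix,
    HaplotypeSpec,
    SampleRecord,
    SimulationSpec,
    SpeciesSpec,
    pairwise_matrix,
    simulate_dataset,
)


def make_set(rows, species=None, groups=None, locus="ITS", ids=None):
    """Build an AlignedSequenceSet from bare row strings."""
    n = len(rows)
    ids = ids or [f"s{i + 1}" for i in range(n)]
    species = species or ["Species one"] * n
    groups = groups or ["inland"] * n
    return AlignedSequenceSet(
        locus,
        [
            SampleRecord(ids[i], species[i], groups[i], rows[i])
            for i in range(n)
        ],
    )


def explicit_matrix(values, ids=None):
    v = np.asarray(values, dtype=float)
    ids = ids or [f"s{i + 1}" for i in range(v.shape[0])]
    return DistanceMatrix(ids, v)


@pytest.fixture
def three_species_sim():
    """Three well-separated species, habitat-structured, no gaps."""
    spec = SimulationSpec(
        species=tuple(
            SpeciesSpec(
                f"Species {k}",
                n_inland=6,
                n_coastal=3,
                haplotypes=(
                    HaplotypeSpec(0.002, "both", 3.0),
                    HaplotypeSpec(0.006, "inland", 1.0),
                    HaplotypeSpec(0.010, "coastal", 1.0),
                ),
            )
            for k in "abc"
        ),
        length=700,
        seed=20260926,
    )
    return simulate_dataset(spec)


@pytest.fixture
def three_species_matrix(three_species_sim):
    return pairwise_matrix(three_species_sim.sequences)
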