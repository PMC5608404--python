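"""Generator correctness: K80 mutation, truth tables, reproducibility."""

import math

import numpy as np
import pytest

from halobarcode import (
    HaplotypeSpec,
    SimulationSpec,
    SpeciesSpec,
    compare_sites,
    haplotype_table,
    k2p_distance,
    mutate_k80,
    pairwise_matrix,
    simulate_dataset,
    theta,
)
from halobarcode.synthetic_data import inject_gaps, random_sequence


class TestMutateK80:
    def test_zero_distance_identity(self):
        rng = np.random.default_rng(0)
        anc = random_sequence(500, rng)
        assert mutate_k80(anc, 0.0, 2.0, rng) == anc

    def test_estimator_recovers_distance(self):
        rng = np.random.default_rng(1)
        anc = random_sequence(10_000, rng)
        ests = []
        for _ in range(200):
            child = mutate_k80(anc, 0.05, 2.0, rng)
            ests.append(k2p_distance(compare_sites(anc, child)))
        ests = np.array(ests)
        se = ests.std(ddof=1) / math.sqrt(len(ests))
        assert abs(ests.mean() - 0.05) < 3 * se

    def test_large_kappa_suppresses_transversions(self):
        rng = np.random.default_rng(2)
        anc = random_sequence(20_000, rng)
        child = mutate_k80(anc, 0.05, 1e6, rng)
        cmp = compare_sites(anc, child)
        assert cmp.Q < 1e-3
        assert cmp.P > 0.03


def _simple_spec(seed=5, **kw):
    return SimulationSpec(
        species=(
            SpeciesSpec(
                "Chenopodium album",
                n_inland=7,
                n_coastal=3,
                haplotypes=(
                    HaplotypeSpec(0.003, "both", 2.0),
                    HaplotypeSpec(0.012, "coastal", 1.0),
                ),
            ),
        ),
        seed=seed,
        **kw,
    )


class TestSimulateDataset:
    def test_single_haplotype_collapses_everywhere(self):
        spec = SimulationSpec(
            species=(
                SpeciesSpec("Sp a", 6, 4, (HaplotypeSpec(0.004),)),
            ),
            seed=3,
        )
        sim = simulate_dataset(spec)
        t = haplotype_table(sim.sequences).set_index("group")
        assert list(t["b"]) == [1, 1, 1]

    def test_truth_haplotype_counts_match_module(self):
        sim = simulate_dataset(_simple_spec())
        got = haplotype_table(sim.sequences, gap_mode="include")
        truth = sim.group_haplotypes
        merged = got.merge(truth, on=["species", "group"], suffixes=("", "_truth"))
        assert (merged["a"] == merged["a_truth"]).all()
        assert (merged["b"] == merged["b_truth"]).all()

    def test_coastal_private_haplotype_increases_combined(self):
        spec = SimulationSpec(
            species=(
                SpeciesSpec(
                    "Sp a",
                    6,
                    4,
                    (
                        HaplotypeSpec(0.002, "inland"),
                        HaplotypeSpec(0.012, "coastal"),
                    ),
                ),
            ),
            seed=17,
        )
        t = simulate_dataset(spec).group_haplotypes.set_index("group")
        assert t.loc["combined", "b"] == t.loc["inland", "b"] + 1

    def test_expected_theta_close_to_recovered(self):
        """Recovered mean pairwise K2P approaches the truth expectation."""
        spec = SimulationSpec(
            species=(
                SpeciesSpec(
                    "Sp a",
                    12,
                    8,
                    (HaplotypeSpec(0.004, "both"), HaplotypeSpec(0.015, "coastal")),
                ),
            ),
            length=8000,  # long sequences shrink estimator noise
            seed=11,
        )
        sim = simulate_dataset(spec)
        m = pairwise_matrix(sim.sequences)
        got = theta(m, sim.sequences.sample_ids)
        want = float(sim.expected_theta["expected_theta"].iloc[0])
        # binomial sampling noise at L=8000: a few 1e-4 on this scale
        assert got == pytest.approx(want, abs=5e-4 + 0.15 * want)

    def test_infeasible_spec_rejected(self):
        spec = SimulationSpec(
            species=(
                SpeciesSpec(
                    "Sp a", 5, 0, (HaplotypeSpec(0.004, "coastal"),)
                ),
            ),
            seed=1,
        )
        with pytest.raises(ValueError, match="coastal"):
            simulate_dataset(spec)

    def test_barcode_gap_enforced(self):
        with pytest.raises(ValueError, match="interspecific"):
            SimulationSpec(
                species=(
                    SpeciesSpec("Sp a", 3, 0, (HaplotypeSpec(0.2),)),
                ),
                interspecific_divergence=0.15,
                seed=1,
            )

    def test_bit_reproducible_under_seed(self):
        a = simulate_dataset(_simple_spec(seed=9))
        b = simulate_dataset(_simple_spec(seed=9))
        assert a.sequences.samples == b.sequences.samples
        assert a.assignments.equals(b.assignments)
        c = simulate_dataset(_simple_spec(seed=10))
        assert c.sequences.samples != a.sequences.samples

    def test_gap_injection_exercises_masking(self):
        sim = simulate_dataset(_simple_spec())
        rng = np.random.default_rng(4)
        gapped = inject_gaps(sim.sequences, 0.05, rng)
        assert any("-" in s.row for s in gapped.samples)
        m = pairwise_matrix(gapped)  # must still be computable
        assert m.n_undefined_pairs == 0

    def test_well_separated_species_identified_end_to_end(self):
        spec = SimulationSpec(
            species=tuple(
                SpeciesSpec(f"Species {k}", 4, 2, (HaplotypeSpec(0.002),))
                for k in "abc"
            ),
            seed=21,
        )
        sim = simulate_dataset(spec)
        m = pairwise_matrix(sim.sequences)
        from halobarcode import best_close_match, discrimination_rate, neighbor_joining

        s = best_close_match(m, sim.sequences.species_map, 0.03)
        assert s.percentages["correct"] == 100.0
        t = neighbor_joining(m, sim.sequences.species_map)
        rate, _ = discrimination_rate(t, missing_support="full", unrooted=True)
        assert rate == 100.0
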