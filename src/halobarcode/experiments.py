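"""Canned simulation experiments used for validation and reporting.

The central one contrasts two species of equal sample size (N = 20, of
which one coastal sample) and equal expected mean pairwise diversity:

* ``rare_variant_spec`` — two common low-divergence inland haplotypes plus
  ONE divergent coastal-private haplotype carried by the single coastal
  sample (frequency 1/N). This emulates a widespread species whose coastal
  salt-marsh population harbours a private, diverged lineage.
* ``matched_uniform_spec`` — two equally frequent haplotypes available in
  both habitats, with their divergence chosen analytically so the expected
  mean pairwise distance equals the rare-variant species'.

The directional claim under test: the rare habitat-private variant inflates
the combined haplotype count and pushes the minimum sufficient sample size
(n_min) upward relative to the uniform population.
"""

from __future__ import annotations

from dataclasses import dataclass

from .distance import pairwise_matrix
from .saturation import saturation_curve
from .synthetic_data import (
    HaplotypeSpec,
    SimulationSpec,
    SpeciesSpec,
    simulate_dataset,
)

N_INLAND, N_COASTAL = 19, 1

#: The rare-variant species' haplotype layout (divergences in subs/site).
_COMMON_D, _MINOR_D, _RARE_D = 0.002, 0.004, 0.03
_COMMON_W, _MINOR_W = 2.0, 1.0


def expected_theta_rare() -> float:
    """Closed-form expected mean pairwise distance of the rare-variant
    species: inland pairs differ with probability 2*w1*w2/(w1+w2)^2 at
    distance d1+d2; each inland-coastal pair sits at d_rare + E[d_inland]."""
    n = N_INLAND + N_COASTAL
    pairs_total = n * (n - 1) / 2
    pairs_inland = N_INLAND * (N_INLAND - 1) / 2
    w = _COMMON_W + _MINOR_W
    p_diff = 2 * _COMMON_W * _MINOR_W / w**2
    e_inland_pair = p_diff * (_COMMON_D + _MINOR_D)
    e_d_inland = (_COMMON_W * _COMMON_D + _MINOR_W * _MINOR_D) / w
    cross = N_INLAND * N_COASTAL * (_RARE_D + e_d_inland)
    return (pairs_inland * e_inland_pair + cross) / pairs_total


def rare_variant_spec(seed: int, length: int = 600) -> SimulationSpec:
    return SimulationSpec(
        species=(
            SpeciesSpec(
                "Rare variant sp",
                N_INLAND,
                N_COASTAL,
                (
                    HaplotypeSpec(_COMMON_D, "inland", _COMMON_W),
                    HaplotypeSpec(_MINOR_D, "inland", _MINOR_W),
                    HaplotypeSpec(_RARE_D, "coastal", 1.0),
                ),
            ),
        ),
        length=length,
        seed=seed,
    )


def matched_uniform_spec(seed: int, length: int = 600) -> SimulationSpec:
    # two equal haplotypes: P(different) = 1/2 at distance 2*d_u -> theta = d_u
    d_u = expected_theta_rare()
    return SimulationSpec(
        species=(
            SpeciesSpec(
                "Uniform sp",
                N_INLAND,
                N_COASTAL,
                (
                    HaplotypeSpec(d_u, "both", 1.0),
                    HaplotypeSpec(d_u, "both", 1.0),
                ),
            ),
        ),
        length=length,
        seed=seed,
    )


@dataclass
class RareVariantOutcome:
    n_min_rare: int
    n_min_uniform: int
    combined_gain: int  # combined haplotype count minus inland count (rare sp)
    rare_wins: bool  # haplotype count increased AND n_min strictly larger


def run_rare_variant_trial(seed: int, replicates: int = 20) -> RareVariantOutcome:
    """One paired simulation; both species share the base seed."""
    outs = []
    for spec in (rare_variant_spec(seed), matched_uniform_spec(seed)):
        sim = simulate_dataset(spec)
        matrix = pairwise_matrix(sim.sequences)
        curve = saturation_curve(
            matrix,
            sim.sequences.sample_ids,
            species=spec.species[0].name,
            replicates=replicates,
            seed=seed + 1,
        )
        n_min = curve.n_min if curve.n_min is not None else curve.N
        outs.append((n_min, sim))
    (n_rare, sim_rare), (n_uni, _) = outs
    t = sim_rare.group_haplotypes.set_index("group")
    gain = int(t.loc["combined", "b"] - t.loc["inland", "b"])
    return RareVariantOutcome(
        n_min_rare=n_rare,
        n_min_uniform=n_uni,
        combined_gain=gain,
        rare_wins=(gain >= 1 and n_rare > n_uni),
    )


def rare_variant_win_rate(n_trials: int, master_seed: int) -> tuple[float, list[RareVariantOutcome]]:
    """Fraction of paired trials where the rare-variant species needs a
    strictly larger minimum sample AND shows the haplotype-count gain."""
    outcomes = [
        run_rare_variant_trial(master_seed + 1000 * (k + 1)) for k in range(n_trials)
    ]
    rate = sum(o.rare_wins for o in outcomes) / n_trials
    return rate, outcomes
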