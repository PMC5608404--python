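"""Ground-truth simulator: habitat-structured multi-species alignments.

Sequences evolve under the Kimura 1980 (K80) two-parameter substitution
model — the generative dual of the K2P estimator — with uniform base
composition. Each species gets an ancestor drawn by mutating a shared root
sequence, each haplotype is realized by mutating the species ancestor at
its nominal divergence, and samples are assigned to haplotypes by weighted
sampling that respects habitat availability (a coastal-private haplotype
can only be drawn by coastal samples). No indels are simulated by default,
which keeps the haplotype truth exact; a gap-injection option exists solely
to exercise site-masking code paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .sequence_io import AlignedSequenceSet, SampleRecord

_BASES = np.array(list("ACGT"))

AVAILABILITIES = ("inland", "coastal", "both")


@dataclass(frozen=True)
class HaplotypeSpec:
    """One intraspecific variant: divergence from the species ancestor
    (expected substitutions/site), habitat availability, frequency weight."""

    divergence: float
    availability: str = "both"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.availability not in AVAILABILITIES:
            raise ValueError(f"availability must be one of {AVAILABILITIES}")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    n_inland: int
    n_coastal: int
    haplotypes: tuple[HaplotypeSpec, ...]

    def __post_init__(self) -> None:
        if self.n_inland < 0 or self.n_coastal < 0:
            raise ValueError("sample counts must be >= 0")
        if self.n_inland + self.n_coastal == 0:
            raise ValueError(f"species {self.name!r} has no samples")
        if not self.haplotypes:
            raise ValueError(f"species {self.name!r} has no haplotypes")


@dataclass(frozen=True)
class SimulationSpec:
    """Full dataset recipe; defaults match realistic barcode data:
    600 bp sequences, transition/transversion ratio 2, intraspecific
    divergences on the 0.00-0.03 scale and interspecific divergence well
    above them (a clean barcode gap, overridable for hard cases)."""

    species: tuple[SpeciesSpec, ...]
    length: int = 600
    kappa: float = 2.0
    interspecific_divergence: float = 0.15
    seed: int = 0
    locus: str = "ITS"
    require_barcode_gap: bool = True

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.require_barcode_gap:
            dmax = max(
                (h.divergence for sp in self.species for h in sp.haplotypes),
                default=0.0,
            )
            if self.interspecific_divergence <= dmax:
                raise ValueError(
                    "interspecific divergence must exceed the largest "
                    "intraspecific divergence (set require_barcode_gap=False "
                    "to construct hard cases)"
                )


def k80_substitution_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each specific transversion)) at distance ``d``.

    Exact K80 transition probabilities with alpha/beta = kappa and
    d = (alpha + 2*beta) * t.
    """
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e_tv = math.exp(-4.0 * bt)
    e_ts = math.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv_each = 0.25 - 0.25 * e_tv
    return p_ts, p_tv_each


def mutate_k80(ancestor: str, d: float, kappa: float, rng: np.random.Generator) -> str:
    """Evolve a sequence to evolutionary distance ``d`` under K80.

    Each site substitutes independently using the exact K80 transition
    probabilities, so the expected estimated K2P distance back to the
    ancestor is ~d.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if d == 0:
        return ancestor
    p_ts, p_tv = k80_substitution_probs(d, kappa)
    codes = np.searchsorted(np.array(list("ACGT")), np.array(list(ancestor)))
    # A=0, C=1, G=2, T=3; transition partner = (c + 2) % 4,
    # transversion partners = (c + 1) % 4 and (c + 3) % 4
    u = rng.random(len(codes))
    out = codes.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts] = (codes[ts] + 2) % 4
    out[tv1] = (codes[tv1] + 1) % 4
    out[tv2] = (codes[tv2] + 3) % 4
    return "".join(_BASES[out])


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


@dataclass
class SimulatedDataset:
    """The alignment plus its ground truth."""

    sequences: AlignedSequenceSet
    assignments: pd.DataFrame  # sample_id, species, group, haplotype (1-based spec index)
    expected_theta: pd.DataFrame  # species, expected_theta (from realized assignment)
    group_haplotypes: pd.DataFrame  # species, group, a, b (distinct realized sequences)
    spec: SimulationSpec = field(repr=False, default=None)


def _available(spec: SpeciesSpec, group: str) -> list[int]:
    return [
        i
        for i, h in enumerate(spec.haplotypes)
        if h.availability in ("both", group)
    ]


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Realize a :class:`SimulationSpec` into sequences plus truth tables.

    Species ancestors are mutated copies of one shared root, each at half
    the interspecific divergence, so ancestor pairs sit near the nominal
    interspecific distance. Bit-reproducible under a fixed seed.
    """
    for sp in spec.species:
        for grp, n in (("inland", sp.n_inland), ("coastal", sp.n_coastal)):
            if n == 0 and any(h.availability == grp for h in sp.haplotypes):
                raise ValueError(
                    f"species {sp.name!r}: {grp}-only haplotype but n_{grp}=0"
                )
        for grp, n in (("inland", sp.n_inland), ("coastal", sp.n_coastal)):
            if n > 0 and not _available(sp, grp):
                raise ValueError(
                    f"species {sp.name!r}: {n} {grp} samples requested but no "
                    f"haplotype is available in that habitat"
                )

    rng = np.random.default_rng(spec.seed)
    root = random_sequence(spec.length, rng)
    samples: list[SampleRecord] = []
    assign_rows = []
    theta_rows = []
    hap_rows = []
    for si, sp in enumerate(spec.species):
        ancestor = mutate_k80(root, spec.interspecific_divergence / 2.0, spec.kappa, rng)
        hap_seqs = [
            mutate_k80(ancestor, h.divergence, spec.kappa, rng) for h in sp.haplotypes
        ]
        chosen: list[tuple[str, int]] = []  # (group, haplotype index)
        for grp, n in (("inland", sp.n_inland), ("coastal", sp.n_coastal)):
            avail = _available(sp, grp)
            if n == 0:
                continue
            w = np.array([sp.haplotypes[i].weight for i in avail], dtype=float)
            draws = rng.choice(len(avail), size=n, p=w / w.sum())
            chosen.extend((grp, avail[k]) for k in draws)
        abbrev = "".join(w[0] for w in sp.name.split())[:4] or f"sp{si}"
        for k, (grp, hap) in enumerate(chosen):
            sid = f"{abbrev}{si}_{k + 1:03d}"
            samples.append(
                SampleRecord(sample_id=sid, species=sp.name, group=grp, row=hap_seqs[hap])
            )
            assign_rows.append(
                {"sample_id": sid, "species": sp.name, "group": grp, "haplotype": hap + 1}
            )
        # expected theta from the realized assignment: a pair of samples on
        # haplotypes i != j sits at expected distance d_i + d_j (independent
        # paths through the ancestor); same haplotype -> identical sequence.
        hap_of = [h for _, h in chosen]
        pair_exp = [
            0.0
            if hap_of[a] == hap_of[b]
            else sp.haplotypes[hap_of[a]].divergence + sp.haplotypes[hap_of[b]].divergence
            for a, b in combinations(range(len(hap_of)), 2)
        ]
        theta_rows.append(
            {
                "species": sp.name,
                "expected_theta": float(np.mean(pair_exp)) if pair_exp else math.nan,
            }
        )
        # truth haplotype counts = distinct realized sequences per subset
        for grp in ("inland", "coastal", "combined"):
            members = [
                hap_seqs[h] for g, h in chosen if grp == "combined" or g == grp
            ]
            hap_rows.append(
                {
                    "species": sp.name,
                    "group": grp,
                    "a": len(members),
                    "b": len(set(members)),
                }
            )

    dataset = AlignedSequenceSet(spec.locus, samples)
    return SimulatedDataset(
        sequences=dataset,
        assignments=pd.DataFrame(assign_rows),
        expected_theta=pd.DataFrame(theta_rows),
        group_haplotypes=pd.DataFrame(hap_rows),
        spec=spec,
    )


def inject_gaps(
    aset: AlignedSequenceSet, rate: float, rng: np.random.Generator
) -> AlignedSequenceSet:
    """Replace a random fraction of residues with gaps (masking exerciser).

    Invalidates the exact haplotype truth; intended only for testing
    site-exclusion code paths.
    """
    new = []
    for s in aset.samples:
        mask = rng.random(len(s.row)) < rate
        row = "".join("-" if m else c for c, m in zip(s.row, mask))
        new.append(SampleRecord(s.sample_id, s.species, s.group, row))
    return AlignedSequenceSet(aset.locus, new)
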