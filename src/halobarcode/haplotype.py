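"""Haplotype collapsing, the species-by-habitat haplotype table, and
haplotype-proportional subsampling.

Collapsing mirrors DnaSP's default treatment of unphased haploid marker
sequences: under ``exclude_sites`` (the default) every alignment column
containing a gap, N, or ambiguity code in ANY retained row is removed once,
then identical remaining rows share a haplotype. Because the removed
columns depend on which rows are present, collapsing is performed
independently within the inland group, within the coastal group, and within
the combined set — which is why the combined haplotype count can be smaller
than the sum of the group counts and can even differ from a naive union.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AlignmentError, ReconciliationError, SubsampleError
from .sequence_io import GROUPS, AlignedSequenceSet

GAP_MODES = ("exclude_sites", "include")
_MISSING = set("-N" + "RYSWKMBDHV")


def collapse_haplotypes(
    aset: AlignedSequenceSet, gap_mode: str = "exclude_sites"
) -> dict[str, int]:
    """Map each sample id to a haplotype index (1-based, first-occurrence order)."""
    if gap_mode not in GAP_MODES:
        raise ValueError(f"unknown gap_mode {gap_mode!r}; expected one of {GAP_MODES}")
    rows = [s.row for s in aset.samples]
    if gap_mode == "exclude_sites":
        length = len(rows[0])
        keep = [
            i for i in range(length) if not any(r[i] in _MISSING for r in rows)
        ]
        if not keep:
            raise AlignmentError(
                f"all {length} sites excluded by gap/missing masking; "
                "no comparable positions remain"
            )
        rows = ["".join(r[i] for i in keep) for r in rows]
    index: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for sample, row in zip(aset.samples, rows):
        if row not in index:
            index[row] = len(index) + 1
        assignment[sample.sample_id] = index[row]
    return assignment


def haplotype_count(aset: AlignedSequenceSet, gap_mode: str = "exclude_sites") -> int:
    return len(set(collapse_haplotypes(aset, gap_mode).values()))


def haplotype_table(
    aset: AlignedSequenceSet, gap_mode: str = "exclude_sites"
) -> pd.DataFrame:
    """Sample size (a) and haplotype count (b) per species and habitat group.

    Rows: one per species per group in (inland, coastal, combined).
    Collapsing is repeated independently inside each subset, so site masks
    may differ between the groups and the combined set.
    """
    bad = {s.group for s in aset.samples} - set(GROUPS)
    if bad:
        raise ReconciliationError(
            f"haplotype table requires a known group for every sample; "
            f"found {sorted(bad)}"
        )
    records = []
    for species in aset.species_names():
        sp = aset.filter_species(species)
        for group in (*GROUPS, "combined"):
            members = (
                sp.samples
                if group == "combined"
                else [s for s in sp.samples if s.group == group]
            )
            if members:
                sub = AlignedSequenceSet(sp.locus, members)
                b = haplotype_count(sub, gap_mode)
            else:
                b = 0
            records.append(
                {"species": species, "group": group, "a": len(members), "b": b}
            )
    return pd.DataFrame(records)


def proportional_subsample(
    aset: AlignedSequenceSet,
    target_n: int,
    seed: int,
    gap_mode: str = "exclude_sites",
    allow_loss: bool = False,
) -> AlignedSequenceSet:
    """Shrink a set to ``target_n`` samples, proportionally per haplotype.

    Quotas are allocated by largest-remainder (Hamilton) rounding of each
    haplotype's share, with every haplotype guaranteed at least one
    representative when ``target_n`` >= number of haplotypes (each floor is
    clamped to 1 before the remainder seats are settled). Ties among equal
    remainders go to the larger haplotype, then first-occurrence order.
    Members within a haplotype are chosen uniformly at random.
    """
    n = len(aset)
    if target_n > n:
        raise SubsampleError(f"target_n={target_n} exceeds sample size {n}")
    if target_n == n:
        return aset
    assignment = collapse_haplotypes(aset, gap_mode)
    haps: dict[int, list[str]] = {}
    for sid in aset.sample_ids:  # keeps first-occurrence order
        haps.setdefault(assignment[sid], []).append(sid)
    h = len(haps)
    if target_n < h:
        if not allow_loss:
            raise SubsampleError(
                f"target_n={target_n} is below the haplotype count {h}; "
                "cannot preserve every haplotype (pass allow_loss=True to drop)"
            )
    order = list(haps)  # haplotype indices in first-occurrence order
    sizes = np.array([len(haps[k]) for k in order], dtype=float)
    quotas = sizes * target_n / n
    alloc = np.floor(quotas).astype(int)
    if target_n >= h:
        alloc = np.maximum(alloc, 1)
    alloc = np.minimum(alloc, sizes.astype(int))
    diff = target_n - int(alloc.sum())
    # settle remaining seats (or excess from the >=1 clamp) deterministically
    def _rank(i):  # larger remainder first, then larger haplotype, then order
        return (-(quotas[i] - alloc[i]), -sizes[i], i)

    while diff != 0:
        if diff > 0:
            cands = [i for i in range(h) if alloc[i] < sizes[i]]
            i = min(cands, key=_rank)
            alloc[i] += 1
            diff -= 1
        else:
            cands = [i for i in range(h) if alloc[i] > (1 if target_n >= h else 0)]
            # remove from the largest surplus over quota
            i = min(cands, key=lambda i: (-(alloc[i] - quotas[i]), sizes[i], -i))
            alloc[i] -= 1
            diff += 1

    rng = np.random.default_rng(seed)
    chosen: set[str] = set()
    for i, k in enumerate(order):
        members = haps[k]
        take = int(alloc[i])
        if take:
            picked = rng.choice(len(members), size=take, replace=False)
            chosen.update(members[p] for p in picked)
    return aset.subset([sid for sid in aset.sample_ids if sid in chosen])
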