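"""Aligned-FASTA + sidecar-metadata I/O, newick trees, and tabular output.

An aligned sequence set is the universal input of the pipeline: one locus,
pre-aligned rows, and one metadata record per sample giving its species and
habitat group (``inland`` or ``coastal``; samples without a group are kept
as ``unassigned`` and only participate in group-agnostic operations).

Metadata lives in a sidecar TSV (columns ``sample_id``, ``species``,
``group``, ``locus``) rather than being packed into FASTA headers, so the
FASTA header is the bare sample id and no header dialect guessing is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, ReconciliationError, SequenceParseError

GROUPS = ("inland", "coastal")
UNASSIGNED = "unassigned"

#: Residues accepted in an aligned row. IUPAC ambiguity codes and N are
#: retained on read and treated as missing by downstream site filters.
IUPAC_AMBIGUITY = set("RYSWKMBDHV")
VALID_RESIDUES = set("ACGT-N") | IUPAC_AMBIGUITY


@dataclass(frozen=True)
class SampleRecord:
    """One aligned sequence with its metadata."""

    sample_id: str
    species: str
    group: str
    row: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS and self.group != UNASSIGNED:
            raise ReconciliationError(
                f"sample {self.sample_id!r}: unknown group {self.group!r} "
                f"(expected one of {GROUPS} or {UNASSIGNED!r})"
            )


@dataclass
class AlignedSequenceSet:
    """Aligned sequences for one locus with per-sample metadata.

    Invariants enforced on construction: all rows share one length >= 1,
    sample ids are unique, every sample carries a species label.
    """

    locus: str
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        if not self.samples:
            raise AlignmentError(f"locus {self.locus!r}: empty sequence set")
        lengths = {len(s.row) for s in self.samples}
        if len(lengths) != 1:
            raise AlignmentError(
                f"locus {self.locus!r}: rows have differing lengths {sorted(lengths)}"
            )
        if 0 in lengths:
            raise AlignmentError(f"locus {self.locus!r}: zero-length alignment")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ReconciliationError(f"duplicate sample ids: {dupes}")
        for s in self.samples:
            bad = [(i, c) for i, c in enumerate(s.row) if c not in VALID_RESIDUES]
            if bad:
                pos, char = bad[0]
                raise SequenceParseError(
                    f"sample {s.sample_id!r}: unknown residue {char!r} at "
                    f"alignment column {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def alignment_length(self) -> int:
        return len(self.samples[0].row)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def species_map(self) -> dict[str, str]:
        return {s.sample_id: s.species for s in self.samples}

    @property
    def group_map(self) -> dict[str, str]:
        return {s.sample_id: s.group for s in self.samples}

    def subset(self, sample_ids) -> "AlignedSequenceSet":
        """Samples restricted to ``sample_ids``, preserving input order."""
        wanted = set(sample_ids)
        missing = wanted - set(self.sample_ids)
        if missing:
            raise ReconciliationError(f"unknown sample ids: {sorted(missing)}")
        return AlignedSequenceSet(
            self.locus, [s for s in self.samples if s.sample_id in wanted]
        )

    def filter_group(self, groups) -> "AlignedSequenceSet":
        """Samples whose habitat group is in ``groups``."""
        kept = [s for s in self.samples if s.group in set(groups)]
        if not kept:
            raise AlignmentError(
                f"locus {self.locus!r}: no samples in groups {sorted(set(groups))}"
            )
        return AlignedSequenceSet(self.locus, kept)

    def filter_species(self, species: str) -> "AlignedSequenceSet":
        kept = [s for s in self.samples if s.species == species]
        if not kept:
            raise ReconciliationError(f"no samples for species {species!r}")
        return AlignedSequenceSet(self.locus, kept)

    def species_names(self) -> list[str]:
        """Species in first-occurrence order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.species, None)
        return list(seen)


def _clean_row(raw: str, sample_id: str) -> str:
    row = raw.upper().replace("U", "T")
    for i, c in enumerate(row):
        if c not in VALID_RESIDUES:
            raise SequenceParseError(
                f"sample {sample_id!r}: unknown residue {c!r} at column {i + 1}"
            )
    return row


def read_metadata(metadata_path) -> pd.DataFrame:
    """Read the sidecar metadata TSV; missing group becomes ``unassigned``."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "species"}
    missing = required - set(meta.columns)
    if missing:
        raise SequenceParseError(
            f"metadata {metadata_path}: missing columns {sorted(missing)}"
        )
    if "group" not in meta.columns:
        meta["group"] = UNASSIGNED
    meta["group"] = meta["group"].fillna(UNASSIGNED)
    if "locus" not in meta.columns:
        meta["locus"] = ""
    if meta["sample_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise ReconciliationError(f"metadata: duplicate sample ids {dupes}")
    return meta


def read_alignment(fasta_path, metadata_path, locus: str | None = None) -> AlignedSequenceSet:
    """Read an aligned FASTA plus its metadata TSV into one validated set.

    FASTA ids and metadata ``sample_id`` values must match exactly (after
    optionally restricting the metadata to one ``locus``); any id present on
    one side only raises a reconciliation error naming it.
    """
    meta = read_metadata(metadata_path)
    if locus is not None:
        meta = meta[meta["locus"] == locus]
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"{fasta_path}: no FASTA records")
    fasta_ids = [r.id for r in records]
    meta_ids = list(meta["sample_id"])
    only_fasta = sorted(set(fasta_ids) - set(meta_ids))
    only_meta = sorted(set(meta_ids) - set(fasta_ids))
    if only_fasta or only_meta:
        parts = []
        if only_fasta:
            parts.append(f"in FASTA but not metadata: {only_fasta}")
        if only_meta:
            parts.append(f"in metadata but not FASTA: {only_meta}")
        raise ReconciliationError("; ".join(parts))
    by_id = meta.set_index("sample_id")
    locus_name = locus if locus is not None else (by_id["locus"].iloc[0] or "locus")
    samples = [
        SampleRecord(
            sample_id=r.id,
            species=str(by_id.loc[r.id, "species"]),
            group=str(by_id.loc[r.id, "group"]),
            row=_clean_row(str(r.seq), r.id),
        )
        for r in records
    ]
    return AlignedSequenceSet(locus_name, samples)


def write_alignment(aset: AlignedSequenceSet, fasta_path, metadata_path) -> None:
    """Write the set back to aligned FASTA + metadata TSV (round-trip safe)."""
    with open(fasta_path, "w") as fh:
        for s in aset.samples:
            fh.write(f">{s.sample_id}\n{s.row}\n")
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in aset.samples],
            "species": [s.species for s in aset.samples],
            "group": [s.group for s in aset.samples],
            "locus": aset.locus,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Support-annotated trees


@dataclass
class SupportTree:
    """A rooted/unrooted topology whose tips are sample ids.

    Internal-node supports are normalized to the [0, 1] fraction scale: if
    any raw support exceeds 1 the whole tree is treated as percent-scaled
    (MrBayes posterior fractions and bootstrap percentages both occur in the
    wild). ``tip_species`` maps every tip label to its species.
    """

    tree: dendropy.Tree
    tip_species: dict[str, str] = field(default_factory=dict)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def supports(self) -> list[float]:
        return [
            n.support
            for n in self.tree.preorder_internal_node_iter()
            if getattr(n, "support", None) is not None
        ]


def _parse_support(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        return None


def read_tree(newick_path_or_string, metadata=None, species_map: dict[str, str] | None = None) -> SupportTree:
    """Read a newick tree; reconcile tips against metadata or a species map.

    ``metadata`` may be a metadata TSV path or DataFrame; alternatively a
    prebuilt ``species_map`` (tip label -> species) is accepted. Internal
    node labels are interpreted as supports and normalized to [0, 1].
    """
    src = str(newick_path_or_string)
    try:
        if "(" in src:  # newick string
            tree = dendropy.Tree.get(
                data=src, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=src, schema="newick", preserve_underscores=True
            )
    except Exception as exc:  # dendropy raises assorted error types
        raise SequenceParseError(f"malformed newick: {exc}") from exc

    if species_map is None:
        if metadata is None:
            raise ReconciliationError("read_tree needs metadata or a species_map")
        meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
        species_map = dict(zip(meta["sample_id"], meta["species"]))

    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    unknown = sorted(set(tips) - set(species_map))
    if unknown:
        raise ReconciliationError(f"tree tips not in metadata: {unknown}")

    raw = []
    for node in tree.preorder_internal_node_iter():
        sup = _parse_support(node.label)
        node.support = sup
        if sup is not None:
            raw.append(sup)
    if any(s < 0 for s in raw):
        raise SequenceParseError("negative support value in tree")
    if any(s > 1 for s in raw):  # percent convention: rescale the whole tree
        if any(s > 100 for s in raw):
            raise SequenceParseError("support value above 100 in tree")
        for node in tree.preorder_internal_node_iter():
            if node.support is not None:
                node.support = node.support / 100.0
    return SupportTree(tree=tree, tip_species={t: species_map[t] for t in tips})


# ---------------------------------------------------------------------------
# Tabular / matrix text output

_FMT = "%.17g"  # shortest-exact float text: numeric round-trips are lossless


def write_matrix(matrix, path) -> None:
    """Write a square distance matrix as TSV with id header row/column.

    Undefined entries are written as ``NA``.
    """
    ids = matrix.sample_ids
    values = matrix.values
    if len(ids) == 0:
        raise AlignmentError("refusing to write an empty matrix")
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(ids) + "\n")
        for i, sid in enumerate(ids):
            cells = [
                "NA" if math.isnan(values[i, j]) else _FMT % values[i, j]
                for j in range(len(ids))
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_matrix(path):
    """Read a matrix written by :func:`write_matrix`; returns (ids, ndarray)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    ids = [str(c) for c in df.columns]
    if ids != [str(i) for i in df.index]:
        raise SequenceParseError(f"{path}: matrix header row and column disagree")
    return ids, df.to_numpy(dtype=float)


def write_table(table: pd.DataFrame, path, float_format: str = _FMT) -> None:
    """Write a result table as TSV; refuses to write an empty table."""
    if table is None or len(table) == 0:
        raise AlignmentError("refusing to write an empty table")
    table.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
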