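"""Tree-based species discrimination plus a neighbor-joining fixture builder.

A species with two or more tips counts as discriminated when some node's
clade contains all of and only that species' tips AND that node's support
exceeds the cutoff (strictly greater than, default 0.95 — "over 95%").
The discrimination rate is the percentage of multi-tip species that are
discriminated; singleton species are reported separately and by default
excluded from both numerator and denominator.

The neighbor-joining builder exists to construct test fixtures from distance
matrices; inference of supported trees is out of scope (trees arrive as
support-annotated newick input).
"""

from __future__ import annotations

import numpy as np

from .distance import DistanceMatrix
from .errors import ReconciliationError, UndefinedDistanceError
from .sequence_io import SupportTree, read_tree


def _clade_leafsets(stree: SupportTree):
    """(frozenset of tip labels, support) for every internal node."""
    out = []
    for node in stree.tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        out.append((leaves, getattr(node, "support", None)))
    return out


def discrimination_rate(
    stree: SupportTree,
    support_cutoff: float = 0.95,
    singletons: str = "exclude",
    outgroup: tuple[str, ...] = (),
    missing_support: str = "fail",
    unrooted: bool = False,
) -> tuple[float, dict[str, str]]:
    """Species discrimination rate from a support-annotated tree.

    Parameters
    ----------
    support_cutoff : support must be strictly greater than this.
    singletons : "exclude" (default) or "count-as-fail".
    outgroup : tip labels pruned before clade evaluation (the tree is
        rerooted above their attachment first when present).
    missing_support : "fail" (an unsupported node never discriminates) or
        "full" (treat absent supports as 1.0 — for topologies, such as
        neighbor-joining fixtures, that carry no support values).
    unrooted : evaluate monophyly on splits (either side of a bipartition),
        for trees whose root is an arbitrary trifurcation. A tree with a
        multifurcating root and no outgroup is refused unless this is set.

    Returns
    -------
    (rate_percent, per_species) where per_species maps each species to
    "discriminated", "not_discriminated" or "singleton".
    """
    if singletons not in ("exclude", "count-as-fail"):
        raise ValueError("singletons must be 'exclude' or 'count-as-fail'")
    if missing_support not in ("fail", "full"):
        raise ValueError("missing_support must be 'fail' or 'full'")

    tree = stree.tree
    if (
        not unrooted
        and not outgroup
        and len(tree.seed_node.child_nodes()) > 2
    ):
        raise ValueError(
            "tree looks unrooted (multifurcating root): declare an outgroup "
            "to root it, or pass unrooted=True for split-based evaluation"
        )
    if outgroup:
        og = set(outgroup)
        unknown = og - set(stree.tip_labels)
        if unknown:
            raise ReconciliationError(f"outgroup tips not in tree: {sorted(unknown)}")
        tree.is_rooted = True
        mrca_taxa = [l.taxon for l in tree.leaf_node_iter() if l.taxon.label in og]
        if len(mrca_taxa) < len(set(stree.tip_labels)):
            node = tree.mrca(taxa=mrca_taxa)
            if node is not tree.seed_node:
                tree.reroot_at_edge(node.edge, update_bipartitions=False)
        keep = [l.taxon for l in tree.leaf_node_iter() if l.taxon.label not in og]
        tree.retain_taxa(keep)

    tip_species = {
        t: s for t, s in stree.tip_species.items() if t not in set(outgroup)
    }
    species_tips: dict[str, set[str]] = {}
    for tip, sp in tip_species.items():
        species_tips.setdefault(sp, set()).add(tip)

    clades = _clade_leafsets(stree)
    all_tips = frozenset(tip_species)
    per_species: dict[str, str] = {}
    for sp, tips in species_tips.items():
        if len(tips) < 2:
            per_species[sp] = "singleton"
            continue
        ok = False
        for leaves, support in clades:
            hit = leaves == tips or (unrooted and all_tips - leaves == tips)
            if hit:
                if support is None:
                    support = 1.0 if missing_support == "full" else None
                if support is not None and support > support_cutoff:
                    ok = True
                    break
        per_species[sp] = "discriminated" if ok else "not_discriminated"

    n_disc = sum(1 for v in per_species.values() if v == "discriminated")
    if singletons == "exclude":
        denom = sum(1 for v in per_species.values() if v != "singleton")
    else:
        denom = len(per_species)
    if denom == 0:
        raise ValueError("no multi-tip species to evaluate")
    return 100.0 * n_disc / denom, per_species


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou & Nei agglomeration) — fixture plumbing


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=()):
        self.label = label
        self.children = list(children)  # (child, branch_length)


def _newick(node: _Node) -> str:
    if not node.children:
        return node.label
    inner = ",".join(f"{_newick(c)}:{bl:.10g}" for c, bl in node.children)
    return f"({inner})"


def neighbor_joining(
    matrix: DistanceMatrix, species_map: dict[str, str] | None = None
) -> SupportTree:
    """Deterministic Saitou–Nei neighbor joining; supports are absent.

    Ties in the Q-criterion are broken by the lowest (i, j) index pair in
    the current working order. Refuses matrices with undefined entries.
    """
    ids = list(matrix.sample_ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    if matrix.n_undefined_pairs:
        pairs = matrix.undefined_pairs()[:5]
        raise UndefinedDistanceError(
            f"matrix has undefined entries (e.g. {pairs}); "
            "neighbor joining refuses undefined distances"
        )
    d = matrix.values.astype(float).copy()
    nodes = [_Node(label=s) for s in ids]
    active = list(range(len(ids)))

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin over the upper triangle in row-major order = lowest (i, j)
        iu = np.triu_indices(n, k=1)
        k = int(np.argmin(q[iu]))
        ai, aj = int(iu[0][k]), int(iu[1][k])
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = dij - li
        parent = _Node(children=[(nodes[active[ai]], li), (nodes[active[aj]], lj)])
        # distances from the new node to the remaining ones
        new_row = np.array(
            [0.5 * (sub[ai, m] + sub[aj, m] - dij) for m in range(n)]
        )
        gi, gj = active[ai], active[aj]
        d = np.pad(d, ((0, 1), (0, 1)))
        new_idx = d.shape[0] - 1
        for m, g in enumerate(active):
            d[new_idx, g] = d[g, new_idx] = new_row[m]
        d[new_idx, new_idx] = 0.0
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [new_idx]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = _Node(
        children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    )
    newick = _newick(root) + ";"
    smap = species_map if species_map is not None else {s: s for s in ids}
    return read_tree(newick, species_map=smap)


def split_set(stree: SupportTree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical frozensets of tip labels.

    Each split is represented by the side NOT containing the
    lexicographically smallest tip, so rootings agree.
    """
    tips = frozenset(stree.tip_labels)
    anchor = min(tips)
    out: set[frozenset[str]] = set()
    for leaves, _support in _clade_leafsets(stree):
        side = leaves if anchor not in leaves else tips - leaves
        if 2 <= len(side) <= len(tips) - 2:
            out.add(frozenset(side))
    return out
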