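"""Distance-based phylogeny for parvalbumin panels, with leaf annotation.

The tree's role here is an annotation scaffold: epitope-count statistics are
laid out against the evolutionary relationships of the panel (beta- vs
alpha-lineage parvalbumins cluster apart, and allergenicity follows the
lineage).  Distances come from a supplied multiple alignment (pairwise
deletion of gapped columns; p-distance or Poisson correction), trees from
neighbor joining with a deterministic tie-break, and supports from column
bootstrap.  An externally produced Newick tree is accepted wherever a tree
is consumed.

Trees are ``skbio.TreeNode`` objects; the NJ agglomeration itself is
written out so its tie-break (lexicographically smallest label pair) and
negative-branch handling (clamp to zero, shift the remainder to the sibling
edge) are explicit and reproducible.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .epitopes import EpitopeCountRow, EpitopeError

__all__ = [
    "PhylogenyError",
    "GAP_CHARS",
    "msa_to_distances",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "robinson_foulds",
    "annotate_leaves",
    "midpoint_root",
    "write_newick",
    "read_newick",
]

GAP_CHARS = frozenset("-.")

ANNOTATION_COLUMNS = [
    "passthrough_linear80",
    "passthrough_3depi",
    "n_positive",
    "n_positive_2m",
    "n_negative",
    "n_negative_2m",
]


class PhylogenyError(ValueError):
    pass


# --------------------------------------------------------------------------
# Distances
# --------------------------------------------------------------------------


def msa_to_distances(
    aligned: Sequence[tuple[str, str]],
    model: str = "poisson_corrected",
) -> DistanceMatrix:
    """Pairwise distances from an alignment, with pairwise gap deletion.

    For each pair, columns where either member holds a gap are skipped;
    p = mismatches / compared columns.  ``model`` is ``"p_distance"`` (p
    itself) or ``"poisson_corrected"`` (-ln(1 - p), the multiple-hit
    correction under a Poisson substitution model).
    """
    if model not in {"p_distance", "poisson_corrected"}:
        raise PhylogenyError(f"unknown distance model {model!r}")
    if len(aligned) < 2:
        raise PhylogenyError("need at least two aligned sequences")
    ids = [sid for sid, _ in aligned]
    if len(set(ids)) != len(ids):
        raise PhylogenyError("duplicate sequence ids in alignment")
    lengths = {len(seq) for _, seq in aligned}
    if len(lengths) != 1:
        raise PhylogenyError("aligned sequences differ in length")
    seqs = [seq.upper() for _, seq in aligned]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            compared = 0
            mismatches = 0
            for x, y in zip(seqs[i], seqs[j]):
                if x in GAP_CHARS or y in GAP_CHARS:
                    continue
                compared += 1
                if x != y:
                    mismatches += 1
            if compared == 0:
                raise PhylogenyError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = mismatches / compared
            if model == "p_distance":
                dist = p
            else:
                if p >= 1.0:
                    raise PhylogenyError(
                        f"saturated pair {ids[i]!r}/{ids[j]!r}: p = 1 has no "
                        "Poisson-corrected distance"
                    )
                dist = -math.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids)


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor-joining agglomeration, deterministic under ties.

    When several pairs minimize the Q criterion, the pair whose (sorted)
    subtree labels are lexicographically smallest is joined; an internal
    node inherits the smallest leaf label beneath it for this purpose.
    Negative limb lengths are clamped to zero and the remainder shifted to
    the sibling edge, so all branch lengths are >= 0.  The result is the
    unrooted NJ tree, represented with a trifurcating root.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise PhylogenyError("neighbor joining needs at least 3 taxa")

    nodes: dict[str, TreeNode] = {name: TreeNode(name=name) for name in ids}
    # tie-break key per active node: smallest leaf label in its subtree
    key: dict[str, str] = {name: name for name in ids}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            dist[frozenset((a, b))] = float(dm[a, b])
    active = list(ids)
    counter = 0

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best_pair: Optional[tuple[str, str]] = None
        best_q = math.inf
        best_key: tuple[str, str] = ("", "")
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * d(a, b) - r[a] - r[b]
                pair_key = tuple(sorted((key[a], key[b])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and pair_key < best_key
                ):
                    best_q, best_pair, best_key = q, (a, b), pair_key
        assert best_pair is not None
        a, b = best_pair
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (n - 2))
        lb = d(a, b) - la
        if la < 0:
            la, lb = 0.0, d(a, b)
        if lb < 0:
            la, lb = d(a, b), 0.0
        parent = TreeNode()
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = la, lb
        parent.extend([child_a, child_b])
        new_id = f"__internal_{counter}"
        counter += 1
        nodes[new_id] = parent
        key[new_id] = min(key[a], key[b])
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_id, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = [c for c in active if c not in (a, b)] + [new_id]

    # Join the final three around a trifurcating root.
    a, b, c = sorted(active, key=lambda x: key[x])
    la = max(0.0, 0.5 * (d(a, b) + d(a, c) - d(b, c)))
    lb = max(0.0, 0.5 * (d(a, b) + d(b, c) - d(a, c)))
    lc = max(0.0, 0.5 * (d(a, c) + d(b, c) - d(a, b)))
    root = TreeNode()
    for name, length in ((a, la), (b, lb), (c, lc)):
        node = nodes.pop(name)
        node.length = length
        root.append(node)
    return root


# --------------------------------------------------------------------------
# Bipartitions, Robinson-Foulds, bootstrap
# --------------------------------------------------------------------------


def bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """The non-trivial bipartitions (internal edges) of an unrooted tree.

    Each bipartition is the unordered pair {side, complement} of tip-name
    sets, so comparisons are rooting-invariant.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    splits: set[frozenset[frozenset[str]]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset((side, other)))
    return splits


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of splits."""
    if {t.name for t in t1.tips()} != {t.name for t in t2.tips()}:
        raise PhylogenyError("trees have different tip sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def bootstrap_support(
    aligned: Sequence[tuple[str, str]],
    n_replicates: int,
    seed: int,
    model: str = "poisson_corrected",
) -> TreeNode:
    """NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement per replicate; each
    internal edge of the full-data tree is annotated (``node.support``, in
    percent) with the fraction of replicate trees containing the same
    bipartition.  Fully seeded, hence reproducible.
    """
    if n_replicates < 1:
        raise PhylogenyError("n_replicates must be >= 1")
    ncols = len(aligned[0][1]) if aligned else 0
    if ncols < 2:
        raise PhylogenyError("alignment must have at least 2 columns")
    tree = neighbor_joining(msa_to_distances(aligned, model))
    target = {split: 0 for split in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    ids = [sid for sid, _ in aligned]
    seq_arr = np.array([list(seq.upper()) for _, seq in aligned])
    for _ in range(n_replicates):
        idx = rng.integers(0, ncols, size=ncols)
        resampled = ["".join(row) for row in seq_arr[:, idx]]
        rep_tree = neighbor_joining(
            msa_to_distances(list(zip(ids, resampled)), model)
        )
        rep_splits = bipartitions(rep_tree)
        for split in target:
            if split in rep_splits:
                target[split] += 1
    all_tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        split = frozenset((side, all_tips - side))
        if split in target:
            node.support = 100.0 * target[split] / n_replicates
    return tree


# --------------------------------------------------------------------------
# Annotation, rooting, Newick I/O
# --------------------------------------------------------------------------


def annotate_leaves(
    tree: TreeNode, rows: Iterable[EpitopeCountRow]
) -> pd.DataFrame:
    """Leaf-order table of the six mapped data points.

    Rows follow the tree's tip traversal order (so the table reads top to
    bottom alongside a drawn tree), with columns: the two pass-through
    percent identities, then the four epitope counts.  Every leaf must have
    a count row; the input order of ``rows`` is irrelevant.
    """
    by_id: dict[str, EpitopeCountRow] = {}
    for r in rows:
        if r.sequence_id in by_id:
            raise EpitopeError(f"duplicate count row for {r.sequence_id!r}")
        by_id[r.sequence_id] = r
    records = []
    for tip in tree.tips():
        row = by_id.get(tip.name)
        if row is None:
            raise PhylogenyError(f"no count row for leaf {tip.name!r}")
        records.append(
            {
                "sequence_id": tip.name,
                "passthrough_linear80": row.passthrough_linear80,
                "passthrough_3depi": row.passthrough_3depi,
                "n_positive": row.n_positive,
                "n_positive_2m": row.n_positive_2m,
                "n_negative": row.n_negative,
                "n_negative_2m": row.n_negative_2m,
            }
        )
    return pd.DataFrame(records, columns=["sequence_id", *ANNOTATION_COLUMNS]).set_index(
        "sequence_id"
    )


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Midpoint-rooted copy, for display; the NJ tree itself is unrooted."""
    return tree.root_at_midpoint()


def _format_length(length: Optional[float]) -> str:
    return "" if length is None else f":{length:.6f}"


def _to_newick(node: TreeNode) -> str:
    if node.is_tip():
        return f"{node.name}{_format_length(node.length)}"
    inner = ",".join(_to_newick(c) for c in node.children)
    support = getattr(node, "support", None)
    label = "" if support is None else format(support, "g")
    return f"({inner}){label}{_format_length(node.length)}"


def write_newick(tree: TreeNode, path) -> None:
    """Write Newick with bootstrap supports as internal-node labels."""
    with open(path, "w") as fh:
        fh.write(_to_newick(tree) + ";\n")


def read_newick(path) -> TreeNode:
    """Read Newick; numeric internal-node labels become ``node.support``."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
            else:
                node.name = None
    return tree
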