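"""Desk-scale phylogenetic-resolution checks for predicted amplicons.

The marker-resolution question is whether the amplified fragment carries
enough signal to recover the relationships a full-length tree shows.  This
module answers it with distance methods: p-distances between aligned
fragments, a deterministic neighbor-joining tree, and Robinson-Foulds
congruence between trees.  Maximum-likelihood inference is deliberately out
of scope; alignments and distance matrices are written in standard formats
so external ML tools can take over.

Trees are :class:`skbio.TreeNode` objects (newick I/O comes for free).
"""

from __future__ import annotations

import itertools

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .core import SequenceError, SequenceRecord


def pairwise_pdistance(records: list[SequenceRecord]) -> DistanceMatrix:
    """p-distances between aligned sequences, gaps excluded pairwise.

    For each pair, alignment columns where either sequence has a gap are
    dropped from that pair's denominator; a pair left with zero comparable
    sites is an error.
    """
    if len(records) < 2:
        raise SequenceError("need at least two sequences")
    ids = [r.id for r in records]
    arr = np.array([list(r.seq.upper()) for r in records])
    if arr.ndim != 2:
        raise SequenceError("sequences are not aligned (unequal lengths)")
    n = len(records)
    out = np.zeros((n, n))
    gap = arr == "-"
    for i, j in itertools.combinations(range(n), 2):
        ok = ~(gap[i] | gap[j])
        m = int(ok.sum())
        if m == 0:
            raise SequenceError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
        p = float((arr[i, ok] != arr[j, ok]).sum()) / m
        out[i, j] = out[j, i] = p
    return DistanceMatrix(out, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree with deterministic tie-breaking.

    Standard Saitou-Nei agglomeration; when several pairs minimize the Q
    criterion the lexicographically smallest (id, id) pair is joined, so the
    topology is independent of input order.  Negative branch-length
    estimates are clamped to zero.  The returned tree is the usual rooted
    representation of an unrooted topology (the final edge is split at the
    root).
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise SequenceError("neighbor joining needs at least 3 taxa")
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate taxon ids")
    d: dict[str, dict[str, float]] = {
        a: {b: float(dm[a, b]) for b in ids if b != a} for a in ids
    }
    nodes: dict[str, TreeNode] = {a: TreeNode(name=a) for a in ids}
    counter = itertools.count(1)
    active = sorted(ids)
    while len(active) > 2:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (n - 2) * d[a][b] - r[a] - r[b]
            key = (q, min(a, b), max(a, b))
            if best is None or key < best:
                best = key
        _, a, b = best
        la = d[a][b] / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[a][b] - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        u = f"__nj{next(counter)}"
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        nodes[u] = TreeNode(children=[na, nb])
        d[u] = {}
        for k in active:
            if k in (a, b):
                continue
            duk = max((d[a][k] + d[b][k] - d[a][b]) / 2, 0.0)
            d[u][k] = duk
            d[k][u] = duk
        del d[a], d[b]
        active = sorted(k for k in active if k not in (a, b)) + [u]
        active.sort()
    a, b = sorted(active)
    na, nb = nodes[a], nodes[b]
    half = max(d[a][b] / 2, 0.0)
    na.length = nb.length = half
    return TreeNode(children=[na, nb])


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted topology.

    Each internal edge splits the leaves in two; the split is canonicalized
    as the side not containing a fixed reference leaf.
    """
    tips = sorted(t.name for t in tree.tips())
    all_tips = frozenset(tips)
    ref = tips[0]
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if len(clade) < 2 or len(clade) > len(tips) - 2:
            continue
        side = clade if ref not in clade else all_tips - clade
        if 2 <= len(side) <= len(tips) - 2:
            out.add(side)
    return out


def rf_distance(a: TreeNode, b: TreeNode) -> int:
    """Robinson-Foulds symmetric difference of unrooted bipartitions."""
    ta = frozenset(t.name for t in a.tips())
    tb = frozenset(t.name for t in b.tips())
    if ta != tb:
        raise SequenceError(
            f"leaf sets differ; only in first: {sorted(ta - tb)}, "
            f"only in second: {sorted(tb - ta)}"
        )
    return len(_bipartitions(a) ^ _bipartitions(b))


def clade_recovery_fraction(reference: TreeNode, test: TreeNode) -> float:
    """Fraction of the reference tree's bipartitions present in `test`."""
    ref = _bipartitions(reference)
    if not ref:
        return 1.0
    return len(ref & _bipartitions(test)) / len(ref)


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    """PHYLIP-flavoured TSV: ids in first column, full symmetric matrix."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for i, a in enumerate(dm.ids):
            row = "\t".join(f"{dm.data[i, j]:.6f}" for j in range(len(dm.ids)))
            fh.write(f"{a}\t{row}\n")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
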