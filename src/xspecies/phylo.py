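"""p-distances and neighbor-joining trees from aligned protein sequences.

The comparative stage of the pipeline: given a multiple alignment of
deduced amino-acid sequences (one taxon per homolog, e.g. a ripening
transcription factor across fleshy-fruit species), compute uncorrected
p-distances with pairwise gap deletion and build an unrooted
neighbor-joining phylogram.  Branch lengths are in residue substitutions
per site.  Trees are :class:`skbio.TreeNode` objects serialized as Newick.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode

GAP = "-"


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Aligned FASTA -> list of (label, sequence); validates the alignment."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    validate_alignment(records)
    return records


def validate_alignment(records: list[tuple[str, str]]) -> None:
    if len(records) < 3:
        raise ValueError(f"alignment needs >= 3 taxa, got {len(records)}")
    labels = [lab for lab, _ in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels in alignment")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences must have equal length, got lengths {sorted(lengths)}")


def p_distance_matrix(alignment: list[tuple[str, str]]) -> DistanceMatrix:
    """Uncorrected p-distance with pairwise gap deletion.

    ``d[i][j]`` = differing positions / positions where neither sequence has
    a gap.  A pair with zero comparable positions is an error.  p-distances
    lie in [0, 1] and may violate the triangle inequality.
    """
    validate_alignment(alignment)
    labels = [lab for lab, _ in alignment]
    seqs = np.array([list(seq) for _, seq in alignment])
    not_gap = seqs != GAP
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = not_gap[i] & not_gap[j]
            n_comp = int(comparable.sum())
            if n_comp == 0:
                raise ValueError(
                    f"taxa {labels[i]!r} and {labels[j]!r} share no gap-free positions"
                )
            diffs = int((seqs[i][comparable] != seqs[j][comparable]).sum())
            d[i, j] = d[j, i] = diffs / n_comp
    return DistanceMatrix(d, ids=labels)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive distances.

    Iteratively joins the pair minimizing
    ``Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)``; ties are
    broken by the lexicographically smallest sorted label pair, so the
    result is deterministic.  Negative branch lengths are kept as computed
    (clamping would break additivity).  Returns an unrooted tree (root of
    degree 3).
    """
    if isinstance(dm, DistanceMatrix):
        labels = list(dm.ids)
        d = np.array(dm.data, dtype=float)
    else:  # raw (labels, matrix) pair
        labels, d = list(dm[0]), np.array(dm[1], dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    # sort key of each active node: smallest leaf label below it
    keys: list[str] = list(labels)

    while len(nodes) > 3:
        n = len(nodes)
        row_sums = d.sum(axis=1)
        q = (n - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i in range(n) for j in range(i + 1, n)
            if q[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin))
        ]
        _, i, j = min(candidates)
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.empty((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d2[-1, -1] = 0.0
        d = d2
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    # final trifurcation: closed-form three-point branch lengths
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    return TreeNode(children=[a, b, c])


def _to_newick(node: TreeNode) -> str:
    if node.is_tip():
        body = node.name or ""
    else:
        body = "(" + ",".join(_to_newick(c) for c in node.children) + ")"
        if node.name:
            body += node.name
    if node.length is not None:
        body += f":{node.length:.6f}"
    return body


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize with branch lengths at 6 decimal places.

    Negative NJ branch lengths are written as computed (not clamped) and
    reported via a warning so additivity checks stay exact.
    """
    negatives = sum(1 for t in tree.traverse() if t.length is not None and t.length < 0)
    if negatives:
        warnings.warn(f"tree contains {negatives} negative branch length(s); written as computed",
                      stacklevel=2)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_to_newick(tree) + ";\n")


def read_newick(path: str | Path) -> TreeNode:
    """Parse a Newick file; malformed input raises with position information."""
    return TreeNode.read(str(path), format="newick")
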