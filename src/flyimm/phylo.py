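"""Poisson-corrected distances, neighbor joining and bootstrap support.

Mature-peptide alignments of AMP families are turned into pairwise distances
under the Poisson correction d = −ln(1 − p), where p is the proportion of
differing sites among positions where both sequences are ungapped (pairwise
deletion; complete deletion available by flag).  Trees are built by the
Saitou–Nei neighbor-joining algorithm with deterministic tie-breaking (lowest
index pair) and negative branch estimates clamped to zero.  Node support
comes from site resampling: each bootstrap replicate is re-distanced and
re-joined, and support is the percentage of replicates containing each
original bipartition.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode


@dataclass
class Alignment:
    """A protein multiple alignment: unique labels, equal-length rows."""

    labels: list[str]
    rows: list[str]
    gap: str = "-"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels not unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows differ in length")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(labels, rows)

    def resample_sites(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Alignment(list(self.labels), rows)


def poisson_distance(row_i: str, row_j: str, gap: str = "-") -> float:
    """Poisson-corrected distance d = −ln(1 − p) under pairwise gap deletion."""
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    compared = differing = 0
    for a, b in zip(row_i, row_j):
        if a == gap or b == gap:
            continue
        compared += 1
        if a != b:
            differing += 1
    if compared == 0:
        raise ValueError("no comparable (ungapped) sites between the rows")
    p = differing / compared
    if p >= 1.0:
        raise ValueError("saturated pair (p = 1): Poisson distance undefined")
    return -math.log(1.0 - p)


def distance_matrix(
    alignment: Alignment,
    complete_deletion: bool = False,
) -> DistanceMatrix:
    """All-pairs Poisson distances; optional complete deletion of gapped sites."""
    rows = alignment.rows
    if complete_deletion:
        keep = [
            c for c in range(alignment.n_sites)
            if all(r[c] != alignment.gap for r in rows)
        ]
        rows = ["".join(r[c] for c in keep) for r in rows]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_distance(rows[i], rows[j], alignment.gap)
    return DistanceMatrix(d, ids=alignment.labels)


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The pair minimising the Q-criterion is joined at each step; ties go to
    the lowest (i, j) index pair in the current matrix order.  Branch lengths
    follow the standard two-point formulas; negative estimates are clamped to
    0.  Returns an unrooted tree (trifurcating root) as a skbio TreeNode.
    """
    d = np.array(dm.data, dtype=float)
    if d.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.ids]

    def _clamp(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        # Q(i, j) = (n - 2) d_ij - r_i - r_j
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, -1, -1)
        for i in range(n):
            for j in range(i + 1, n):
                if q[i, j] < best[0] - 1e-12:
                    best = (q[i, j], i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = _clamp(li)
        nodes[j].length = _clamp(lj)
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.zeros((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_row[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-way join
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    root = TreeNode(children=list(nodes))
    for node, length in zip(nodes, lengths):
        node.length = _clamp(length)
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf sets (smaller/lexicographic side)."""
    taxa = frozenset(leaf.name for leaf in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(
            (side, other),
            key=lambda s: (len(s), tuple(sorted(s))),
        )
        parts.add(canon)
    return parts


def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    complete_deletion: bool = False,
    max_redraws: int = 10_000,
) -> tuple[TreeNode, int]:
    """NJ tree with bootstrap support values from site resampling.

    Each replicate resamples alignment columns with replacement, recomputes
    Poisson distances and rejoins; the support of an internal node of the
    original tree is the percentage of replicates whose tree contains the
    same bipartition.  Replicates with undefined distances (saturated or
    all-gap pairs) are redrawn; the count of redraws is returned alongside
    the annotated tree.
    """
    tree = neighbor_joining(distance_matrix(alignment, complete_deletion))
    original = bipartitions(tree)
    counts = {part: 0 for part in original}
    rng = np.random.default_rng(seed)
    redraws = 0
    done = 0
    while done < n_replicates:
        replicate = alignment.resample_sites(rng)
        try:
            rep_tree = neighbor_joining(distance_matrix(replicate, complete_deletion))
        except ValueError:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many bootstrap replicates with undefined distances")
            continue
        rep_parts = bipartitions(rep_tree)
        for part in original:
            if part in rep_parts:
                counts[part] += 1
        done += 1

    taxa = frozenset(alignment.labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min((side, other), key=lambda s: (len(s), tuple(sorted(s))))
        node.name = str(round(100.0 * counts[canon] / n_replicates))
    return tree, redraws


def to_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths and integer support labels."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
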