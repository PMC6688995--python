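"""Distance-based phylogeny: conserved-site selection, Jukes-Cantor (JC69)
distances and neighbor-joining tree construction.

The JC69 one-parameter model corrects an observed mismatch proportion p
(computed over conserved — ungapped, unambiguous — alignment columns, with
complete deletion) into an evolutionary distance

    d = -(3/4) ln(1 - (4/3) p),

finite only for p < 3/4.  Neighbor joining (Saitou-Nei) then agglomerates the
distance matrix by repeatedly joining the pair minimizing

    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k),

with ties broken lexicographically on cluster labels for determinism and
negative branch-length estimates clamped to zero (flagged with a warning).
NJ is exact on additive matrices: it recovers the generating topology and all
path lengths.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class SaturationError(ValueError):
    """Observed mismatch proportion at or beyond the JC69 domain (p >= 3/4)."""


def jc69(p: float) -> float:
    """JC69 distance for a mismatch proportion p in [0, 0.75)."""
    if not 0.0 <= p:
        raise ValueError(f"mismatch proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"saturated distance: p = {p} >= 0.75")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def select_conserved_sites(rows: Mapping[str, str]) -> list[int]:
    """0-based indices of columns with no gap and no ambiguity code in any
    row (the conserved-site set under complete deletion)."""
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in rows.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows differ in length")
    (length,) = lengths
    valid = set("ACGT")
    out = []
    for j in range(length):
        if all(row[j].upper() in valid for row in rows.values()):
            out.append(j)
    return out


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("non-symmetric distance matrix")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])


def mismatch_matrix(
    rows: Mapping[str, str], conserved_sites: Sequence[int] | None = None
) -> DistanceMatrix:
    """JC69 distance matrix over the conserved-site columns of an aligned
    nucleotide matrix.  A saturated pair raises with the taxa named."""
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    sites = (
        list(conserved_sites)
        if conserved_sites is not None
        else select_conserved_sites(rows)
    )
    if not sites:
        raise ValueError("zero conserved sites")
    taxa = sorted(rows)
    mat = np.array(
        [[ord(rows[t][j].upper()) for j in sites] for t in taxa], dtype=np.int16
    )
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(mat[i] != mat[j]))
            try:
                d[i, j] = d[j, i] = jc69(p)
            except SaturationError as exc:
                raise SaturationError(
                    f"saturated distance between {taxa[i]!r} and {taxa[j]!r}: "
                    f"p = {p}"
                ) from exc
    return DistanceMatrix(taxa=taxa, values=d)


@dataclass
class Node:
    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    root: Node
    n_leaves: int

    def leaves(self) -> list[str]:
        out: list[str] = []

        def visit(node: Node) -> None:
            if node.is_leaf():
                out.append(node.name)
            for child, _ in node.children:
                visit(child)

        visit(self.root)
        return sorted(out)

    def to_newick(self) -> str:
        def render(node: Node) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(
                f"{render(child)}:{bl:.6f}" for child, bl in node.children
            )
            return f"({inner})"

        return render(self.root) + ";"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Patristic (path) distances between all leaf pairs."""

        def collect(node: Node) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: 0.0}
            merged: dict[str, float] = {}
            groups: list[dict[str, float]] = []
            for child, bl in node.children:
                sub = {k: v + bl for k, v in collect(child).items()}
                groups.append(sub)
                merged.update(sub)
            for ga, gb in itertools.combinations(groups, 2):
                for la, da in ga.items():
                    for lb, db in gb.items():
                        key = (la, lb) if la < lb else (lb, la)
                        result[key] = da + db
            return merged

        result: dict[tuple[str, str], float] = {}
        collect(self.root)
        return result


def _clamp(length: float) -> float:
    if length < 0:
        if length < -1e-12:
            warnings.warn(
                f"negative NJ branch length {length:.6g} clamped to 0",
                stacklevel=3,
            )
        return 0.0
    return length


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with lexicographic tie-breaking.

    Every active cluster is keyed by its lexicographically smallest leaf
    label; the Q-minimizing pair with the smallest (key_i, key_j) wins ties.
    """
    n0 = len(matrix.taxa)
    if n0 < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[str, Node] = {t: Node(name=t) for t in matrix.taxa}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(matrix.taxa):
        for j in range(i + 1, n0):
            b = matrix.taxa[j]
            dist[frozenset((a, b))] = float(matrix.values[i, j])

    active = sorted(nodes)
    while len(active) > 3:
        n = len(active)
        r = {
            a: sum(dist[frozenset((a, b))] for b in active if b != a)
            for a in active
        }
        best = None
        for a, b in itertools.combinations(active, 2):
            key = (a, b) if a < b else (b, a)
            q = (n - 2) * dist[frozenset((a, b))] - r[a] - r[b]
            cand = (q, key)
            if best is None or cand < best:
                best = cand
        _, (a, b) = best
        d_ab = dist[frozenset((a, b))]
        bl_a = _clamp(0.5 * d_ab + (r[a] - r[b]) / (2 * (n - 2)))
        bl_b = _clamp(d_ab - (0.5 * d_ab + (r[a] - r[b]) / (2 * (n - 2))))
        new_key = min(a, b)
        parent = Node(children=[(nodes[a], bl_a), (nodes[b], bl_b)])
        for c in active:
            if c in (a, b):
                continue
            d_new = 0.5 * (
                dist[frozenset((a, c))] + dist[frozenset((b, c))] - d_ab
            )
            dist[frozenset((new_key, c))] = d_new
        active = sorted([c for c in active if c not in (a, b)] + [new_key])
        nodes[new_key] = parent

    if len(active) == 2:
        a, b = active
        d_ab = dist[frozenset((a, b))]
        root = Node(
            children=[(nodes[a], 0.5 * d_ab), (nodes[b], 0.5 * d_ab)]
        )
    else:
        a, b, c = active
        d_ab = dist[frozenset((a, b))]
        d_ac = dist[frozenset((a, c))]
        d_bc = dist[frozenset((b, c))]
        bl_a = _clamp(0.5 * (d_ab + d_ac - d_bc))
        bl_b = _clamp(0.5 * (d_ab + d_bc - d_ac))
        bl_c = _clamp(0.5 * (d_ac + d_bc - d_ab))
        root = Node(
            children=[(nodes[a], bl_a), (nodes[b], bl_b), (nodes[c], bl_c)]
        )
    return PhyloTree(root=root, n_leaves=n0)
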