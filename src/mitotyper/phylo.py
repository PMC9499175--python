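"""Conservative p-distances and neighbor-joining trees.

The distance treats two symbols as identical whenever their IUPAC base
sets share an allele (a Y is identical to a C or a T), which can only
lower divergence estimates.  NJ stands in for a likelihood tree search:
the claim it supports is topological (mitotype clustering), and NJ is
exact on additive distances.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GroupingError, InputError, UndefinedDistanceError
from .mitomodel import LabeledAlignment
from .mitomodel import iupac


def conservative_distance(
    seq_a: str | np.ndarray, seq_b: str | np.ndarray
) -> float:
    """p-distance counting a site as divergent only when the two base sets
    are disjoint; gap columns are excluded from the denominator."""
    a = iupac.encode(seq_a) if isinstance(seq_a, str) else seq_a
    b = iupac.encode(seq_b) if isinstance(seq_b, str) else seq_b
    if len(a) != len(b):
        raise InputError("sequences must be equal length")
    ok = (a != iupac.GAP_CODE) & (b != iupac.GAP_CODE)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedDistanceError("no gap-free columns to compare")
    return float(iupac.SET_MISMATCH[a[ok], b[ok]].sum()) / n


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise InputError("distance matrix must be symmetric with zero diagonal")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


def distance_matrix(alignment: LabeledAlignment) -> DistanceMatrix:
    """All-pairs conservative p-distance matrix."""
    mat = alignment.matrix
    n = alignment.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = conservative_distance(mat[i], mat[j])
    return DistanceMatrix(labels=list(alignment.ids), d=d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_part() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"


@dataclass
class Tree:
    """Unrooted tree represented with an arbitrary internal root (degree 3
    after a standard NJ run)."""

    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def newick(self) -> str:
        return self.root.newick()

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf sets cut off by each internal edge (one side each)."""
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> None:
            for c in node.children:
                out.add(frozenset(c.leaves()))
                walk(c)

        walk(self.root)
        return out

    def is_monophyletic(self, labels: set[str]) -> bool:
        """True when some edge separates exactly ``labels`` from the rest."""
        want = frozenset(labels)
        everything = frozenset(self.leaves())
        if not want or not want < everything:
            return False
        other = everything - want
        parts = self.bipartitions()
        return want in parts or other in parts


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Neighbor joining with deterministic tie-breaking by label order and
    negative branch lengths clamped to zero (excess moved to the sister
    branch)."""
    n = len(matrix.labels)
    if n < 3:
        raise InputError(f"NJ needs at least 3 labels, got {n}")

    nodes = [TreeNode(name=lab) for lab in matrix.labels]
    # sort key per active node: smallest leaf label under it, for stable ties
    keys = list(matrix.labels)
    d = matrix.d.astype(float).copy()
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining ones
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row) - 1] = new_row[:-1]
        d[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # closed-form three-point finish
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    order = sorted((i, j, k), key=lambda x: keys[x])
    return Tree(root=TreeNode(children=[nodes[x] for x in order]))


def exclude_heteroplasmic(alignment: LabeledAlignment) -> LabeledAlignment:
    """Drop every sample carrying any ambiguity symbol (Fig-1-style tree
    input)."""
    mat = alignment.matrix
    ambiguous = ((mat >= 4) & (mat != iupac.GAP_CODE)).any(axis=1)
    keep = [sid for sid, bad in zip(alignment.ids, ambiguous) if not bad]
    if not keep:
        raise GroupingError("all samples show heteroplasmy; nothing left")
    return alignment.subset_samples(keep)


def write_distance_tsv(matrix: DistanceMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(matrix.d, index=matrix.labels, columns=matrix.labels).to_csv(
        path, sep="\t", float_format="%.8g"
    )
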