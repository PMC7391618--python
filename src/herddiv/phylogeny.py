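"""Nei's D_A distances and neighbor-joining trees over breeds.

``D_A = 1 - (1/L) sum_blocks sum_alleles sqrt(x_u * y_u)`` where x and y
are the two breeds' allele-frequency vectors; it ranges from 0
(identical frequency tables) to 1 (disjoint allele sets everywhere) and
is well suited to multi-allelic markers under drift.

The neighbor-joining construction is the classical Saitou-Nei
agglomeration on the Q-criterion with deterministic tie-breaking
(lexicographically smallest taxon pair), so runs are reproducible on degenerate
(e.g. ultrametric equal-distance) inputs. Negative branch-length
estimates are clamped to zero with the deficit moved to the sister edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DataError
from .diversity import BlockAlleleTable

__all__ = ["nei_da", "da_matrix", "PhyloTree", "neighbor_joining",
           "root_with_outgroup", "to_newick"]


def nei_da(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Nei's D_A distance between two allele-frequency tables.

    ``freq_*`` are (n_blocks, n_alleles) arrays whose rows each sum to 1.
    Both breeds must be tabulated over the same block set.
    """
    fa = np.asarray(freq_a, float)
    fb = np.asarray(freq_b, float)
    if fa.shape != fb.shape:
        raise DataError("frequency tables must share the block set")
    if not (np.allclose(fa.sum(axis=1), 1.0) and np.allclose(fb.sum(axis=1), 1.0)):
        raise DataError("allele frequencies must sum to 1 per block")
    return float(1.0 - np.sqrt(fa * fb).sum(axis=1).mean())


def da_matrix(t: BlockAlleleTable) -> pd.DataFrame:
    """Symmetric breed x breed Nei D_A matrix from a block-allele table."""
    freq = t.frequencies()
    b = len(t.breeds)
    m = np.zeros((b, b))
    for i in range(b):
        for j in range(i + 1, b):
            m[i, j] = m[j, i] = nei_da(freq[i], freq[j])
    return pd.DataFrame(m, index=t.breeds, columns=t.breeds)


@dataclass
class PhyloTree:
    """Tree over breed leaves as an undirected weighted adjacency map.

    ``root`` is None for the unrooted NJ output; rooting inserts a
    degree-2 node on the outgroup's pendant edge.
    """

    adjacency: dict[str, dict[str, float]]
    leaves: list[str]
    root: str | None = None
    _counter: int = field(default=0, repr=False)

    def neighbors(self, node: str) -> dict[str, float]:
        return self.adjacency[node]

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths along the unique a-b path."""
        stack = [(a, 0.0, None)]
        while stack:
            node, dist, prev = stack.pop()
            if node == b:
                return dist
            for nxt, w in self.adjacency[node].items():
                if nxt != prev:
                    stack.append((nxt, dist + w, node))
        raise DataError(f"no path between {a!r} and {b!r}")

    def leaf_distance_matrix(self) -> pd.DataFrame:
        n = len(self.leaves)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = self.path_length(self.leaves[i],
                                                    self.leaves[j])
        return pd.DataFrame(m, index=self.leaves, columns=self.leaves)


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    # negative NJ edge: zero it and move the deficit to the sister edge
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def neighbor_joining(d: pd.DataFrame) -> PhyloTree:
    """Saitou-Nei neighbor joining of a symmetric distance matrix.

    For any additive input the produced tree's leaf-to-leaf path lengths
    reproduce the input exactly (up to the negative-length clamp, which
    never fires on additive input).
    """
    labels = list(d.index)
    if len(labels) < 3:
        raise DataError("neighbor joining needs >= 3 taxa")
    m = d.to_numpy(float).copy()
    if not np.allclose(m, m.T, atol=1e-10):
        raise DataError("distance matrix must be symmetric")
    adj: dict[str, dict[str, float]] = {l: {} for l in labels}
    active = list(labels)
    counter = 0

    def connect(a: str, b: str, w: float) -> None:
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    while len(active) > 3:
        n = len(active)
        r = m.sum(axis=1)
        q = (n - 2) * m - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break: lexicographically smallest taxon pair
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((min(active[i], active[j]), max(active[i], active[j]), i, j)
             for i, j in cand if i < j)
        )
        i, j = best[2], best[3]
        li = m[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = m[i, j] - li
        li, lj = _clamp_pair(li, lj)
        counter += 1
        new = f"node{counter}"
        connect(new, active[i], li)
        connect(new, active[j], lj)
        dn = (m[i] + m[j] - m[i, j]) / 2
        keep = [k for k in range(n) if k not in (i, j)]
        m = np.vstack([m[keep][:, keep],
                       dn[keep][None, :]])
        m = np.hstack([m, np.append(dn[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [new]

    # final trifurcation via the three-point formulas
    a, b, c = active
    ia, ib, ic = 0, 1, 2
    la = (m[ia, ib] + m[ia, ic] - m[ib, ic]) / 2
    lb = m[ia, ib] - la
    lc = m[ia, ic] - la
    counter += 1
    hub = f"node{counter}"
    for node, ln in ((a, la), (b, lb), (c, lc)):
        connect(hub, node, max(ln, 0.0))
    return PhyloTree(adjacency=adj, leaves=labels, root=None, _counter=counter)


def root_with_outgroup(t: PhyloTree, outgroup: str) -> PhyloTree:
    """Root the tree at the midpoint of the outgroup's pendant edge."""
    if outgroup not in t.leaves:
        raise DataError(f"unknown outgroup leaf {outgroup!r}")
    adj = {k: dict(v) for k, v in t.adjacency.items()}
    (parent, length), = adj[outgroup].items()
    root = "root"
    del adj[outgroup][parent]
    del adj[parent][outgroup]
    half = length / 2.0
    adj.setdefault(root, {})
    adj[root][outgroup] = half
    adj[outgroup][root] = half
    adj[root][parent] = length - half
    adj[parent][root] = length - half
    return PhyloTree(adjacency=adj, leaves=list(t.leaves), root=root,
                     _counter=t._counter)


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;'\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(t: PhyloTree, root: str | None = None) -> str:
    """Serialize (rooted at ``root``, the stored root, or the last hub)."""
    if root is None:
        root = t.root if t.root is not None else f"node{t._counter}"

    def render(node: str, parent: str | None) -> str:
        children = [n for n in t.adjacency[node] if n != parent]
        if not children:
            return _quote(node)
        inner = ",".join(
            f"{render(c, node)}:{t.adjacency[node][c]:.10g}" for c in children
        )
        label = _quote(node) if node in t.leaves else ""
        return f"({inner}){label}"

    return render(root, None) + ";"
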