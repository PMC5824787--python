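"""Distance-based tree building for the aligned family.

Pairwise distances are p-distances (mismatches over shared ungapped
columns), optionally Poisson-corrected (d = -ln(1 - p)), and the tree is
built by neighbor joining.  The NJ implementation is the canonical
Studier–Keppler O(n^3) algorithm with deterministic tie-breaking (lowest
index pair) so repeated runs on the same input give the same tree.  A
negative branch length produced by the NJ length formula is clamped to
zero and the deficit moved to its sibling branch, preserving the pair's
summed length.

Trees are held in a thin wrapper over :class:`dendropy.Tree`.  Internal
nodes are labeled ``N1..Nk`` in preorder after midpoint rooting, which is
the labeling the ancestral-reconstruction module reports against.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .family import AlignedFamily


class PhyloTree:
    """Rooted-or-not phylogeny with leaf labels and branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
            if not np.isfinite(edge.length) or edge.length < 0:
                raise ValueError(f"invalid branch length {edge.length}")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()

    # -- basic queries -----------------------------------------------------
    @property
    def leaf_labels(self) -> list:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def internal_labels(self) -> list:
        return [nd.label for nd in self.tree.preorder_node_iter()
                if not nd.is_leaf() and nd.label]

    def label_internal_nodes(self, midpoint_root: bool = True) -> None:
        """Midpoint-root (optional) and assign N1..Nk to internal nodes in preorder."""
        if midpoint_root and len(self.leaf_labels) >= 3:
            self._midpoint_root()
        k = 0
        for nd in self.tree.preorder_node_iter():
            if not nd.is_leaf():
                k += 1
                nd.label = f"N{k}"

    def _midpoint_root(self) -> None:
        """Root at the midpoint of the longest leaf-to-leaf path.

        Implemented directly (double traversal for the tree diameter, then
        an edge split) so that the degenerate case where the midpoint
        coincides with an existing node is handled cleanly.
        """
        def neighbors(nd):
            out = [(c, c.edge.length or 0.0) for c in nd.child_nodes()]
            if nd.parent_node is not None:
                out.append((nd.parent_node, nd.edge.length or 0.0))
            return out

        def farthest_leaf(start):
            dist, prev = {start: 0.0}, {start: None}
            stack = [start]
            while stack:
                nd = stack.pop()
                for nb, ln in neighbors(nd):
                    if nb not in dist:
                        dist[nb] = dist[nd] + ln
                        prev[nb] = nd
                        stack.append(nb)
            leaves = [n for n in dist if n.is_leaf()]
            best = max(leaves, key=lambda n: (dist[n], str(n.taxon.label)))
            return best, dist, prev

        any_leaf = next(self.tree.leaf_node_iter())
        a, _, _ = farthest_leaf(any_leaf)
        b, dist, prev = farthest_leaf(a)
        diameter = dist[b]
        if diameter <= 0:
            return
        # walk back from b toward a accumulating the b-side distance
        path = [b]
        while prev[path[-1]] is not None:
            path.append(prev[path[-1]])
        half = diameter / 2.0
        acc = 0.0
        for u, v in zip(path, path[1:]):  # u closer to b
            # edge between u and v; child side holds the length
            child = u if v is u.parent_node else v
            ln = child.edge.length or 0.0
            if acc + ln >= half - 1e-12:
                offset = half - acc  # measured from u along the edge
                if offset <= 1e-12 and not u.is_leaf():
                    self.tree.reroot_at_node(u, update_bipartitions=False)
                elif ln - offset <= 1e-12 and not v.is_leaf():
                    self.tree.reroot_at_node(v, update_bipartitions=False)
                else:
                    if child is u:  # v is the parent: u-side piece = offset
                        l_child, l_parent = offset, ln - offset
                    else:          # u is the parent
                        l_child, l_parent = ln - offset, offset
                    self.tree.reroot_at_edge(child.edge, length1=l_parent,
                                             length2=l_child,
                                             update_bipartitions=False)
                self.tree.is_rooted = True
                return
            acc += ln

    def leaf_to_root_distances(self) -> dict:
        out = {}
        for lf in self.tree.leaf_node_iter():
            d, nd = 0.0, lf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            out[lf.taxon.label] = d
        return out

    def pairwise_leaf_distances(self) -> tuple:
        """(labels, matrix) of patristic leaf-to-leaf distances."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = sorted(t.label for t in self.tree.taxon_namespace)
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                           taxa[labels[j]])
        return labels, m


# ---------------------------------------------------------------------------
# Distances

def protein_distance_matrix(family: AlignedFamily,
                            correction: str = "poisson") -> tuple:
    """Pairwise distances between aligned sequences.

    p-distance = mismatches / shared ungapped columns; the Poisson
    correction d = -ln(1 - p) is applied with p capped at 0.95 so a
    saturated pair stays finite.

    Returns (ids, matrix).
    """
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    ids = list(family.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    seqs = [np.frombuffer(s.encode(), dtype="S1") for s in family.sequences]
    gap = b"-"
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (seqs[i] != gap) & (seqs[j] != gap)
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"no shared ungapped columns between {ids[i]!r} and {ids[j]!r}")
            p = float((seqs[i][shared] != seqs[j][shared]).sum()) / n_shared
            if correction == "poisson":
                p = min(p, 0.95)
                dist = -np.log(1.0 - p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return ids, d


# ---------------------------------------------------------------------------
# Neighbor joining

def build_nj_tree(ids: list, distances: np.ndarray) -> PhyloTree:
    """Neighbor-joining tree from a symmetric non-negative distance matrix.

    Deterministic given input order; on additive matrices the generating
    topology and branch lengths are recovered exactly.
    """
    d = np.asarray(distances, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if np.any(~np.isfinite(d)):
        raise ValueError("distance matrix contains NaN or inf")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in ids:
        nd = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(nd)

    active = list(range(n))
    dm = d.copy()

    def _set_length(node, length):
        node.edge.length = float(length)

    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic: smallest (i, j) index pair among minima
        flat = np.argmin(q)
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = dm[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        lj = max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        _set_length(nodes[i], li)
        _set_length(nodes[j], lj)
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (dm[i, :] + dm[j, :] - dij)
        dm = np.vstack([dm, new_row])
        new_col = np.append(new_row, 0.0)
        dm = np.column_stack([dm, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # final star join of the last three
    a, b, c = active
    la = 0.5 * (dm[a, b] + dm[a, c] - dm[b, c])
    lb = 0.5 * (dm[a, b] + dm[b, c] - dm[a, c])
    lc = 0.5 * (dm[a, c] + dm[b, c] - dm[a, b])
    root = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        _set_length(nodes[idx], max(length, 0.0))
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


def nj_tree_from_family(family: AlignedFamily,
                        correction: str = "poisson") -> PhyloTree:
    ids, d = protein_distance_matrix(family, correction)
    return build_nj_tree(ids, d)
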