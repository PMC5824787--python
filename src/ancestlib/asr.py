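"""Likelihood on trees and marginal ancestral sequence reconstruction.

The alignment likelihood is computed by Felsenstein's pruning algorithm:
partial likelihoods are combined post-order over the tree, with the
transition matrix P(t) = expm(Q t) on every branch and alignment gaps (and
'X') treated as missing data.  Marginal ancestral posteriors come from a
second, pre-order pass: for every internal node the posterior over states
is proportional to the product of the partial likelihoods flowing in from
all incident subtrees, with the equilibrium frequencies entering at the
root — for a reversible model the result does not depend on the root
position.

The MAP (maximum a-posteriori) state per column gives each node's
reconstructed sequence; ties are broken alphabetically (the state order is
alphabetical, so argmax does this) and flagged.  Whether an ancestor has a
residue at all in columns gapped in some descendants is decided by Fitch
parsimony on a binary present/absent character, ties resolved toward
"present".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .family import AlignedFamily
from .models import AA_INDEX, AMINO_ACIDS, SubstitutionModel
from .phylo import PhyloTree

_MISSING = {"-", "X"}


def _leaf_partials(family: AlignedFamily) -> dict:
    """Per-sequence (ncol, 20) indicator partials; gaps/'X' -> all ones."""
    out = {}
    ncol = family.n_columns
    for sid, seq in zip(family.ids, family.sequences):
        p = np.zeros((ncol, 20))
        for c, aa in enumerate(seq):
            if aa in _MISSING:
                p[c, :] = 1.0
            else:
                p[c, AA_INDEX[aa]] = 1.0
        out[sid] = p
    return out


def _check_leaves(family: AlignedFamily, tree: PhyloTree) -> None:
    leaves = set(tree.leaf_labels)
    fam = set(family.ids)
    if leaves != fam:
        missing = sorted(fam - leaves)
        extra = sorted(leaves - fam)
        raise ValueError(
            f"tree/alignment mismatch: missing from tree {missing}, "
            f"not in alignment {extra}")


def _up_pass(family: AlignedFamily, tree: PhyloTree,
             model: SubstitutionModel) -> tuple:
    """Post-order partials.

    Returns (up, messages, logscale) where up[node] is the (ncol, 20)
    partial at the node, messages[child_node] is P(t_child) @ up[child]
    viewed from the parent, and logscale is the (ncol,) accumulated log
    scaling factor.
    """
    leaf_partials = _leaf_partials(family)
    ncol = family.n_columns
    up, messages = {}, {}
    logscale = np.zeros(ncol)
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            up[nd] = leaf_partials[nd.taxon.label]
        else:
            part = np.ones((ncol, 20))
            for child in nd.child_nodes():
                p = model.transition_matrix(child.edge.length or 0.0)
                msg = up[child] @ p.T
                messages[child] = msg
                part = part * msg
            # rescale to avoid underflow on deep trees
            scale = part.max(axis=1)
            scale[scale == 0] = 1.0
            part = part / scale[:, None]
            logscale += np.log(scale)
            up[nd] = part
    return up, messages, logscale


def pruning_loglik(family: AlignedFamily, tree: PhyloTree,
                   model: SubstitutionModel) -> float:
    """Total log-likelihood of the alignment (sum over columns)."""
    _check_leaves(family, tree)
    up, _, logscale = _up_pass(family, tree, model)
    root = tree.tree.seed_node
    site = up[root] @ model.frequencies
    return float(np.sum(np.log(site) + logscale))


@dataclass
class AncestralPosterior:
    """Marginal ancestral state posteriors at every internal node."""

    node_labels: list
    #: node label -> (ncol, 20) posterior; rows sum to 1
    probabilities: dict
    #: node label -> MAP sequence ('-' where the ancestor is called absent)
    map_sequences: dict
    #: node label -> (ncol,) bool, Fitch present/absent call
    present: dict
    #: node label -> (ncol,) bool, True where the MAP state was tied
    ties: dict

    def map_record(self, label: str) -> str:
        return self.map_sequences[label]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in self.node_labels:
            probs = self.probabilities[label]
            for col in range(probs.shape[0]):
                row = {"node": label, "column": col + 1,
                       "present": bool(self.present[label][col]),
                       "map": self.map_sequences[label][col]}
                row.update({aa: probs[col, i]
                            for i, aa in enumerate(AMINO_ACIDS)})
                rows.append(row)
        return pd.DataFrame(rows)


def _fitch_presence(family: AlignedFamily, tree: PhyloTree) -> dict:
    """Binary Fitch parsimony on present/absent, ties toward present."""
    ncol = family.n_columns
    present_leaf = {sid: np.array([aa != "-" for aa in seq])
                    for sid, seq in zip(family.ids, family.sequences)}
    sets = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            s = np.where(present_leaf[nd.taxon.label], 1, 2)  # 1=P, 2=A
            sets[nd] = s.astype(np.int8)
        else:
            children = [sets[c] for c in nd.child_nodes()]
            inter = children[0].copy()
            union = children[0].copy()
            for c in children[1:]:
                inter = inter & c
                union = union | c
            s = np.where(inter != 0, inter, union)
            sets[nd] = s.astype(np.int8)
    calls = {}
    for nd in tree.tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        s = sets[nd]
        if nd.parent_node is None or nd.parent_node.is_leaf():
            # root: prefer present when ambiguous
            call = (s & 1).astype(bool)
        else:
            parent_call = calls[nd.parent_node]
            parent_state = np.where(parent_call, 1, 2)
            keep_parent = (s & parent_state) != 0
            prefer_present = (s & 1) != 0
            call = np.where(keep_parent, parent_call, prefer_present)
        calls[nd] = call.astype(bool)
    return calls


def marginal_asr(family: AlignedFamily, tree: PhyloTree,
                 model: SubstitutionModel) -> AncestralPosterior:
    """Marginal ancestral posteriors, MAP sequences, and presence calls.

    Internal nodes must be labeled (see PhyloTree.label_internal_nodes);
    unlabeled trees are labeled in place with the default scheme.
    """
    _check_leaves(family, tree)
    if not tree.internal_labels:
        tree.label_internal_nodes()
    up, messages, _ = _up_pass(family, tree, model)
    ncol = family.n_columns
    pi = model.frequencies

    out = {}  # node -> outside partial (ncol, 20), includes pi at root
    root = tree.tree.seed_node
    out[root] = np.tile(pi, (ncol, 1))
    for nd in tree.tree.preorder_node_iter():
        if nd is root:
            pass
        else:
            parent = nd.parent_node
            above = out[parent].copy()
            for sib in parent.child_nodes():
                if sib is not nd:
                    above = above * messages[sib]
            p = model.transition_matrix(nd.edge.length or 0.0)
            o = above @ p
            scale = o.max(axis=1)
            scale[scale == 0] = 1.0
            out[nd] = o / scale[:, None]

    presence = _fitch_presence(family, tree)
    labels, probs, maps, present, ties = [], {}, {}, {}, {}
    for nd in tree.tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        label = nd.label
        joint = up[nd] * out[nd]
        norm = joint.sum(axis=1, keepdims=True)
        post = joint / norm
        idx = np.argmax(post, axis=1)
        best = post[np.arange(ncol), idx]
        tie = (np.isclose(post, best[:, None], rtol=1e-12, atol=1e-15)
               .sum(axis=1) > 1)
        pres = presence[nd]
        seq = "".join(AMINO_ACIDS[i] if p else "-"
                      for i, p in zip(idx, pres))
        labels.append(label)
        probs[label] = post
        maps[label] = seq
        present[label] = pres
        ties[label] = tie
    return AncestralPosterior(labels, probs, maps, present, ties)


def rank_ancestral_nodes(post: AncestralPosterior, family: AlignedFamily,
                         target_id: str, active_site_columns=(),
                         sort_by: str = "conservation") -> pd.DataFrame:
    """Rank internal nodes against the target sequence.

    identity: MAP-vs-target identical fraction over columns where the node
    is called present and the target is ungapped.  active_site_conservation:
    fraction of the given alignment columns where the MAP state equals the
    target state.  Default sort: conservation desc, then identity desc.
    """
    target_row = family.row(target_id)
    active = sorted(set(active_site_columns))
    if any(c < 1 or c > family.n_columns for c in active):
        raise ValueError("active-site column outside alignment")
    if not active:
        import warnings
        warnings.warn("empty active-site set; conservation reported as 1.0")
    rows = []
    for label in post.node_labels:
        seq = post.map_sequences[label]
        shared = [(a, t) for a, t in zip(seq, target_row)
                  if a != "-" and t != "-"]
        ident = (sum(1 for a, t in shared if a == t) / len(shared)
                 if shared else 0.0)
        if active:
            cons = sum(1 for c in active
                       if seq[c - 1] != "-" and seq[c - 1] == target_row[c - 1])
            cons /= len(active)
        else:
            cons = 1.0
        rows.append({"node": label, "identity": ident,
                     "active_site_conservation": cons})
    df = pd.DataFrame(rows)
    if sort_by == "conservation":
        df = df.sort_values(["active_site_conservation", "identity", "node"],
                            ascending=[False, False, True])
    elif sort_by == "identity":
        df = df.sort_values(["identity", "active_site_conservation", "node"],
                            ascending=[False, False, True])
    else:
        raise ValueError(f"unknown sort key {sort_by!r}")
    return df.reset_index(drop=True)
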