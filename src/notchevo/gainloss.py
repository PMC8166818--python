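"""Dollo-parsimony reconstruction of gene-family gain and loss.

A gene family's presence/absence pattern over the leaves of a rooted
species tree is explained by a single gain (the family originates once)
followed by the minimal number of independent losses.  Under that model
the gain edge is the edge above the MRCA of the present leaves, and the
loss edges are the stems of the maximal wholly-absent subtrees inside the
gain clade — both unique, so the reconstruction is exact, not heuristic.

Edges are identified by the frozenset of leaf labels below them, which is
stable across tree copies and re-orderings.  Polytomies are accepted;
each child of a polytomy is treated independently during loss
minimisation.  Unrooted trees are rejected rather than auto-rooted.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import dendropy
import pandas as pd

from .errors import ValidationError

EdgeId = frozenset


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def clade_map(tree: dendropy.Tree) -> dict:
    """Map each node to the frozenset of leaf labels below it."""
    mapping: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            mapping[node] = frozenset({node.taxon.label})
        else:
            mapping[node] = frozenset().union(*(mapping[c] for c in node.child_nodes()))
    return mapping


def _require_rooted(tree: dendropy.Tree) -> None:
    if not tree.is_rooted:
        raise ValidationError("gain/loss reconstruction requires a rooted tree")


@dataclasses.dataclass
class GainLossHistory:
    family: str
    gain_edge: EdgeId  # leaf set below the edge above the origin node
    loss_edges: frozenset  # of EdgeId
    implied_presence: dict  # EdgeId (clade) -> 0/1 for every node
    origin_at_root: bool  # gain on the virtual edge above the sampled root

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def dollo_reconstruct(
    tree: dendropy.Tree, presence: Mapping[str, int], family: str = "family"
) -> GainLossHistory:
    """Single-gain, minimum-loss history for one family.

    ``presence`` maps every leaf label to 0/1.  The reconstruction is the
    unique Dollo optimum: gain above the MRCA of present leaves, one loss
    per maximal absent subtree below it.
    """
    _require_rooted(tree)
    clades = clade_map(tree)
    leaves = set(leaf_labels(tree))
    if set(presence) != leaves:
        missing = leaves ^ set(presence)
        raise ValidationError(
            f"{family}: presence vector does not match tree leaves: "
            + ", ".join(sorted(missing))
        )
    present = {l for l, v in presence.items() if v}
    if not present:
        raise ValidationError(f"{family}: all-absent vector has no gain/loss history")

    # Gain: edge above the MRCA of present leaves.
    gain_node = next(
        node
        for node in tree.postorder_node_iter()
        if present <= clades[node]
        and all(not (present <= clades[c]) for c in node.child_nodes())
    )
    gain_clade = clades[gain_node]
    origin_at_root = gain_node is tree.seed_node

    # Losses: stems of maximal wholly-absent subtrees inside the gain clade.
    loss_edges: set = set()

    def walk(node) -> None:
        clade = clades[node]
        if not (clade & present):
            loss_edges.add(clade)
            return
        for child in node.child_nodes():
            walk(child)

    for child in gain_node.child_nodes():
        walk(child)
    if gain_node.is_leaf() and gain_clade != present:
        raise AssertionError("leaf gain node must be present")

    implied = {}
    for node, clade in clades.items():
        inside = clade <= gain_clade
        lost = any(clade <= loss for loss in loss_edges)
        implied[clade] = int(inside and not lost)
    # Sanity: implied leaf states reproduce the input exactly.
    for leaf in leaves:
        assert implied[frozenset({leaf})] == int(leaf in present)
    return GainLossHistory(
        family, gain_clade, frozenset(loss_edges), implied, origin_at_root
    )


def annotate_losses(history: GainLossHistory) -> list[str]:
    """Human-readable loss list, each loss named by its clade's leaves."""
    return sorted("+".join(sorted(clade)) for clade in history.loss_edges)


def gainloss_matrix(
    tree: dendropy.Tree, matrix: pd.DataFrame
) -> list[GainLossHistory]:
    """One Dollo history per family of a families x species 0/1 matrix.

    Families with at least one present species are reconstructed; the
    result is ranked by origin depth (families gained closest to the root
    first, then by descending gain-clade size, then name).
    """
    _require_rooted(tree)
    tree_leaves = set(leaf_labels(tree))
    matrix_species = set(matrix.columns)
    if tree_leaves != matrix_species:
        only_tree = sorted(tree_leaves - matrix_species)
        only_matrix = sorted(matrix_species - tree_leaves)
        raise ValidationError(
            "species mismatch between tree and matrix; "
            f"tree-only: {only_tree}; matrix-only: {only_matrix}"
        )
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths_clade = 0 if parent is None else depths[id(parent)] + 1
        depths[id(node)] = depths_clade
    clade_depth = {clade_map(tree)[n]: depths[id(n)] for n in tree.preorder_node_iter()}

    histories = []
    for family in matrix.index:
        presence = {sp: int(matrix.loc[family, sp]) for sp in matrix.columns}
        if not any(presence.values()):
            continue
        histories.append(dollo_reconstruct(tree, presence, family=family))
    histories.sort(
        key=lambda h: (clade_depth[h.gain_edge], -len(h.gain_edge), h.family)
    )
    return histories


def history_table(histories: Iterable[GainLossHistory]) -> pd.DataFrame:
    """Flat TSV-ready summary of a set of histories."""
    rows = []
    for h in histories:
        rows.append(
            {
                "family": h.family,
                "gain_clade": "+".join(sorted(h.gain_edge)),
                "origin_at_root": int(h.origin_at_root),
                "n_losses": h.n_losses,
                "losses": ";".join(annotate_losses(h)) or "-",
            }
        )
    return pd.DataFrame(
        rows, columns=["family", "gain_clade", "origin_at_root", "n_losses", "losses"]
    )
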