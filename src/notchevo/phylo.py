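"""Distance phylogenetics for paralog-clade analysis.

This module provides a desk-scale tree-building route: gap-fraction
column trimming of a consumed protein alignment, uncorrected p-distances,
neighbor joining, and non-parametric bootstrap support on bipartitions.
It is used to test clade questions — is the mollusc Delta2 set
monophyletic relative to Delta1, which Hes/Hey subtype clade does a query
gene nest in — rather than to produce publication ML trees.

Numerical conventions: NJ ties in the Q matrix are broken by the
lexicographically smallest label pair; negative branch lengths are
clamped to zero with the deficit moved to the sister branch so the
cherry's span is preserved; supports are percentages on internal
bipartitions (edge-based, so they do not depend on rooting).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .config import RunConfig
from .errors import ValidationError
from .io_formats import SequenceRecord, tree_from_string

GAP = "-"


@dataclasses.dataclass
class MultipleAlignment:
    """A consumed protein multiple alignment (equal-length gapped rows)."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValidationError("alignment needs >= 2 rows")
        ncol = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != ncol:
                raise ValidationError(
                    f"row {rec.id!r} has length {len(rec.sequence)}, expected {ncol}"
                )

    @property
    def labels(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence)

    def to_array(self) -> np.ndarray:
        return np.array([list(r.sequence) for r in self.records])

    @classmethod
    def from_array(cls, labels: Sequence[str], arr: np.ndarray) -> "MultipleAlignment":
        return cls(
            [
                SequenceRecord(lab, "", "".join(row), "protein")
                for lab, row in zip(labels, arr)
            ]
        )


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal; NaN = no comparable columns

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0):
            raise ValidationError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.values - self.values.T)) > 1e-12:
                raise ValidationError("distance matrix must be symmetric")

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


def trim_alignment(msa: MultipleAlignment, max_gap_fraction: float) -> MultipleAlignment:
    """Keep exactly the columns whose gap fraction <= max_gap_fraction."""
    if not 0 <= max_gap_fraction <= 1:
        raise ValidationError("max_gap_fraction must be in [0, 1]")
    arr = msa.to_array()
    gap_frac = (arr == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    if not keep.any():
        raise ValidationError(
            "trimming removed every column; raise max_gap_fraction"
        )
    return MultipleAlignment.from_array(msa.labels, arr[:, keep])


def p_distance(msa: MultipleAlignment) -> DistanceMatrix:
    """Uncorrected pairwise distances: mismatches / comparable columns.

    Columns with a gap in either row are excluded per pair; a pair with no
    comparable columns gets NaN (flagged missing, never silently zero).
    """
    arr = msa.to_array()
    n = len(msa.records)
    values = np.zeros((n, n))
    nongap = arr != GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            ncomp = int(both.sum())
            if ncomp == 0:
                values[i, j] = values[j, i] = np.nan
            else:
                mism = int((arr[i, both] != arr[j, both]).sum())
                values[i, j] = values[j, i] = mism / ncomp
    return DistanceMatrix(msa.labels, values)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard NJ agglomeration on a complete distance matrix.

    Returns an unrooted dendropy tree (trifurcating basal node).  Ties in
    the Q criterion pick the lexicographically smallest label pair;
    negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.
    """
    if len(dm.labels) < 3:
        raise ValidationError("neighbor joining needs >= 3 taxa")
    if dm.has_missing:
        raise ValidationError("distance matrix has missing entries")
    labels = list(dm.labels)
    d = dm.values.astype(float).copy()
    # Each active node carries (newick subtree string, first-label key).
    nodes = [(lab, lab) for lab in labels]

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    while len(nodes) > 3:
        n = len(nodes)
        totals = d.sum(axis=1)
        q = (n - 2) * d - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if q[i, j] <= qmin + 1e-12:
                    key = tuple(sorted((nodes[i][1], nodes[j][1])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        newick = f"({nodes[i][0]}:{fmt(li)},{nodes[j][0]}:{fmt(lj)})"
        key = min(nodes[i][1], nodes[j][1])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [(newick, key)]

    # Resolve the final three nodes around a central trifurcation.
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    order = sorted(range(3), key=lambda k: nodes[k][1])
    parts = {a: la, b: lb, c: lc}
    inner = ",".join(f"{nodes[k][0]}:{fmt(parts[k])}" for k in order)
    tree = tree_from_string(f"({inner});")
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap


def bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial leaf-set bipartitions of a tree (rooting-independent)."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits = set()
    clades: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clades[node] = frozenset({node.taxon.label})
        else:
            clades[node] = frozenset().union(*(clades[c] for c in node.child_nodes()))
        side = clades[node]
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({side, other}))
    return splits


@dataclasses.dataclass
class SupportedTree:
    tree: dendropy.Tree  # topology from the full alignment
    support: dict  # bipartition -> percentage in [0, 100]
    reps: int

    def newick_with_support(self) -> str:
        """Newick with integer supports as internal node labels."""
        all_leaves = frozenset(l.taxon.label for l in self.tree.leaf_node_iter())
        clades: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                clades[node] = frozenset({node.taxon.label})
                continue
            clades[node] = frozenset().union(*(clades[c] for c in node.child_nodes()))
            split = frozenset({clades[node], all_leaves - clades[node]})
            if split in self.support:
                node.label = str(int(round(self.support[split])))
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def bootstrap_support(
    msa: MultipleAlignment,
    reps: int,
    seed: int,
    max_gap_fraction: float | None = None,
) -> SupportedTree:
    """Column-resampling bootstrap support for the NJ tree of an alignment.

    Replicate r resamples ``n_columns`` column indices with replacement
    from ``numpy.random.default_rng(seed)`` consumed in replicate order,
    so supports are bit-reproducible per seed.  Support of an internal
    bipartition of the full-alignment tree is the percentage of replicate
    trees containing it.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    work = msa if max_gap_fraction is None else trim_alignment(msa, max_gap_fraction)
    base_tree = neighbor_joining(p_distance(work))
    base_splits = bipartitions(base_tree)
    counts = {split: 0 for split in base_splits}
    rng = np.random.default_rng(seed)
    arr = work.to_array()
    ncol = work.n_columns
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_msa = MultipleAlignment.from_array(work.labels, arr[:, cols])
        rep_dm = p_distance(rep_msa)
        if rep_dm.has_missing:
            continue  # replicate uninformative for some pair; counts unchanged
        rep_splits = bipartitions(neighbor_joining(rep_dm))
        for split in base_splits & rep_splits:
            counts[split] += 1
    support = {split: 100.0 * c / reps for split, c in counts.items()}
    return SupportedTree(base_tree, support, reps)


# ---------------------------------------------------------------------------
# Clade queries


def _clades_of(tree: dendropy.Tree) -> dict:
    clades: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clades[node] = frozenset({node.taxon.label})
        else:
            clades[node] = frozenset().union(*(clades[c] for c in node.child_nodes()))
    return clades


def root_on_outgroup(tree: dendropy.Tree, outgroup_leaf: str) -> dendropy.Tree:
    """Return a copy of the tree rooted on the given outgroup leaf's edge."""
    rooted = tree.clone(depth=1)
    node = rooted.find_node_with_taxon_label(outgroup_leaf)
    if node is None:
        raise ValidationError(f"outgroup leaf {outgroup_leaf!r} not in tree")
    length = node.edge.length
    rooted.reroot_at_edge(
        node.edge,
        length1=None if length is None else length / 2,
        length2=None if length is None else length / 2,
        update_bipartitions=False,
    )
    rooted.is_rooted = True
    return rooted


def is_monophyletic(
    tree: dendropy.Tree, leaf_subset: Sequence[str], outgroup_leaf: str
) -> bool:
    """True iff leaf_subset is exactly a clade after rooting on the outgroup."""
    subset = frozenset(leaf_subset)
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = (subset | {outgroup_leaf}) - labels
    if unknown:
        raise ValidationError(f"unknown leaf label(s): {', '.join(sorted(unknown))}")
    if outgroup_leaf in subset:
        raise ValidationError("outgroup leaf cannot be in the query subset")
    rooted = root_on_outgroup(tree, outgroup_leaf)
    return subset in set(_clades_of(rooted).values())


def assign_subtype_by_clade(
    tree: dendropy.Tree,
    reference_labels: Mapping[str, str],
    queries: Sequence[str] | None = None,
) -> dict:
    """Assign each query leaf the subtype of the reference clade it nests in.

    Walks from the query toward the root; the first ancestor containing
    any reference leaf decides: one reference subtype -> that subtype,
    several -> "ambiguous" (larger clades can only add subtypes).  The
    tree must be rooted (e.g. via :func:`root_on_outgroup`).
    """
    if not reference_labels:
        raise ValidationError("no reference genes supplied")
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = set(reference_labels) - labels
    if missing:
        raise ValidationError(
            f"reference leaves not in tree: {', '.join(sorted(missing))}"
        )
    if queries is None:
        queries = sorted(labels - set(reference_labels))
    clades = _clades_of(tree)
    result = {}
    for query in queries:
        node = tree.find_node_with_taxon_label(query)
        if node is None:
            raise ValidationError(f"query leaf {query!r} not in tree")
        verdict = "ambiguous"
        while node.parent_node is not None:
            node = node.parent_node
            subtypes = {
                reference_labels[l] for l in clades[node] if l in reference_labels
            }
            if subtypes:
                verdict = subtypes.pop() if len(subtypes) == 1 else "ambiguous"
                break
        result[query] = verdict
    return result
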