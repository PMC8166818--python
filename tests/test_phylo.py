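"""Alignment trimming, p-distance, neighbor joining, bootstrap, clades."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from notchevo.errors import ValidationError
from notchevo.io_formats import SequenceRecord, tree_from_string
from notchevo.phylo import (
    DistanceMatrix,
    MultipleAlignment,
    assign_subtype_by_clade,
    bipartitions,
    bootstrap_support,
    is_monophyletic,
    neighbor_joining,
    p_distance,
    root_on_outgroup,
    trim_alignment,
)
from notchevo.synthetic import (
    generate_random_tree,
    planted_split_alignment,
    planted_subtype_alignment,
    tree_distances,
)


def msa_of(rows: dict) -> MultipleAlignment:
    return MultipleAlignment(
        [SequenceRecord(k, "", v, "protein") for k, v in rows.items()]
    )


class TestTrim:
    def test_gap_free_alignment_unchanged(self):
        msa = msa_of({"a": "ACDE", "b": "ACDF"})
        assert trim_alignment(msa, 0.0).to_array().tolist() == msa.to_array().tolist()

    def test_majority_gap_column_removed(self):
        msa = msa_of({"a": "A-", "b": "C-", "c": "D-", "d": "EF"})
        trimmed = trim_alignment(msa, 0.5)
        assert trimmed.n_columns == 1

    def test_threshold_one_is_identity(self):
        msa = msa_of({"a": "A---", "b": "-C--"})
        assert trim_alignment(msa, 1.0).n_columns == 4

    def test_everything_trimmed_is_an_error(self):
        msa = msa_of({"a": "--", "b": "A-"})
        with pytest.raises(ValidationError, match="gap_fraction|raise"):
            trim_alignment(msa, 0.0)


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        d = p_distance(msa_of({"a": "ACDE", "b": "ACDE"}))
        assert d.values[0, 1] == 0

    def test_one_mismatch_in_four_columns(self):
        d = p_distance(msa_of({"a": "AAAA", "b": "AAAT"}))
        assert d.values[0, 1] == pytest.approx(0.25)

    def test_gap_columns_excluded_from_comparison(self):
        d = p_distance(msa_of({"a": "A-AA", "b": "ATAA"}))
        assert d.values[0, 1] == 0

    def test_no_comparable_columns_flagged_missing(self):
        d = p_distance(msa_of({"a": "A--", "b": "-AA"}))
        assert np.isnan(d.values[0, 1]) and d.has_missing

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_triangle_inequality_on_gap_free_alignments(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.choice(list("ACDE"), size=(4, 20))
        d = p_distance(MultipleAlignment.from_array(list("wxyz"), arr)).values
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"], np.array(
            [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]
        ))
        tree = neighbor_joining(d)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                           "C": pytest.approx(3.0)}

    def test_four_taxon_additive_matrix_recovers_split_and_lengths(self):
        d = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
            ),
        )
        tree = neighbor_joining(d)
        split = frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        assert split in bipartitions(tree)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {
            "A": pytest.approx(1.0), "B": pytest.approx(2.0),
            "C": pytest.approx(3.0), "D": pytest.approx(1.0),
        }
        internal = [
            n.edge.length
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.edge.length is not None
        ]
        assert internal == [pytest.approx(1.0)]

    def test_consistency_on_random_additive_matrices(self):
        for seed in range(25):
            tree = generate_random_tree(8, seed=seed)
            recovered = neighbor_joining(tree_distances(tree))
            assert bipartitions(recovered) == bipartitions(tree)

    def test_agrees_with_skbio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        tree = generate_random_tree(7, seed=3)
        dm = tree_distances(tree)
        sk_tree = skbio.tree.nj(
            skbio.DistanceMatrix(dm.values, ids=dm.labels)
        )
        sk_splits = {
            frozenset(
                {
                    frozenset(t.name for t in n.tips()),
                    frozenset(dm.labels) - frozenset(t.name for t in n.tips()),
                }
            )
            for n in sk_tree.non_tips()
        }
        sk_splits = {s for s in sk_splits if min(len(x) for x in s) >= 2}
        mine = bipartitions(neighbor_joining(dm))
        assert sk_splits <= mine

    def test_missing_entries_rejected(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], values))


class TestBootstrap:
    def test_unanimous_alignment_gives_support_100(self):
        msa, truth = planted_split_alignment(
            n_taxa=6, signal_columns=10, private_columns_per_taxon=1, seed=0
        )
        for reps in (1, 25):
            st_tree = bootstrap_support(msa, reps=reps, seed=9)
            assert st_tree.support[truth.payload["split"]] == 100.0

    def test_single_replicate_supports_are_zero_or_hundred(self):
        msa, _ = planted_split_alignment(seed=1)
        st_tree = bootstrap_support(msa, reps=1, seed=2)
        assert set(st_tree.support.values()) <= {0.0, 100.0}

    def test_supports_reproducible_per_seed(self):
        msa, _ = planted_split_alignment(seed=4)
        a = bootstrap_support(msa, reps=20, seed=7)
        b = bootstrap_support(msa, reps=20, seed=7)
        assert a.support == b.support

    def test_newick_carries_integer_support_labels(self):
        msa, _ = planted_split_alignment(n_taxa=6, seed=2)
        st_tree = bootstrap_support(msa, reps=10, seed=1)
        assert ")100" in st_tree.newick_with_support() or ")" in st_tree.newick_with_support()


class TestCladeQueries:
    def test_planted_clade_is_monophyletic(self):
        tree = tree_from_string("((d2a,d2b),(d1a,d1b),og);")
        assert is_monophyletic(tree, ["d2a", "d2b"], "og")
        assert not is_monophyletic(tree, ["d2a", "d1a"], "og")
        assert is_monophyletic(tree, ["d2a", "d2b", "d1a", "d1b"], "og")

    def test_unknown_leaf_is_an_error(self):
        tree = tree_from_string("((a,b),c);")
        with pytest.raises(ValidationError, match="unknown"):
            is_monophyletic(tree, ["a", "z"], "c")

    def test_subtype_recovery_from_planted_alignment(self):
        msa, refs, truth = planted_subtype_alignment(seed=5)
        tree = neighbor_joining(p_distance(msa))
        rooted = root_on_outgroup(tree, truth.payload["outgroup"])
        verdicts = assign_subtype_by_clade(
            rooted, refs, sorted(truth.payload["subtypes"])
        )
        assert verdicts == truth.payload["subtypes"]

    def test_query_basal_to_all_references_is_ambiguous(self):
        tree = tree_from_string("(q,((h1,h2),(y1,y2)));")
        tree.is_rooted = True
        refs = {"h1": "Hes", "h2": "Hes", "y1": "Hey", "y2": "Hey"}
        assert assign_subtype_by_clade(tree, refs, ["q"]) == {"q": "ambiguous"}

    def test_no_references_is_an_error(self):
        tree = tree_from_string("((a,b),c);")
        with pytest.raises(ValidationError, match="reference"):
            assign_subtype_by_clade(tree, {}, ["a"])
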