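"""Dollo gain/loss reconstruction against a brute-force oracle."""

import itertools

import pandas as pd
import pytest

from notchevo.errors import ValidationError
from notchevo.gainloss import (
    annotate_losses,
    clade_map,
    dollo_reconstruct,
    gainloss_matrix,
    leaf_labels,
)
from notchevo.io_formats import tree_from_string
from notchevo.synthetic import (
    MOLLUSC_DELTA2_LOSSES,
    MOLLUSC_GAIN_CLADE,
    generate_random_tree,
    mollusc_presence_matrix,
    mollusc_tree,
    simulate_gainloss,
)


def rooted(newick: str):
    tree = tree_from_string(newick)
    tree.is_rooted = True
    return tree


def brute_force_min_losses(tree, presence):
    """Enumerate all single-gain histories and return the minimum loss count.

    For each candidate gain clade containing all present leaves, losses
    are subsets of clades strictly inside the gain whose union is exactly
    the absent-but-descendant leaf set; the minimum subset size over all
    gains is the Dollo optimum.
    """
    clades = sorted(set(clade_map(tree).values()), key=lambda c: (len(c), sorted(c)))
    present = frozenset(l for l, v in presence.items() if v)
    best = None
    for gain in clades:
        if not present <= gain:
            continue
        absent = gain - present
        if not absent:
            best = 0 if best is None else min(best, 0)
            continue
        # candidate loss edges: clades strictly inside the gain made
        # entirely of absent leaves
        cands = [c for c in clades if c < gain and c <= absent]
        for k in range(1, len(cands) + 1):
            if best is not None and k >= best:
                break
            hit = False
            for combo in itertools.combinations(cands, k):
                union = frozenset().union(*combo)
                if union == absent:
                    best = k if best is None else min(best, k)
                    hit = True
                    break
            if hit:
                break
    return best


class TestDolloExamples:
    def test_all_present_gains_at_root_with_no_losses(self):
        tree = rooted("((A,B),(C,D));")
        h = dollo_reconstruct(tree, {"A": 1, "B": 1, "C": 1, "D": 1})
        assert h.gain_edge == frozenset("ABCD")
        assert h.n_losses == 0 and h.origin_at_root

    def test_cherry_presence_gains_at_cherry(self):
        tree = rooted("((A,B),(C,D));")
        h = dollo_reconstruct(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert h.gain_edge == frozenset("AB") and h.n_losses == 0

    def test_discordant_presence_needs_two_losses(self):
        tree = rooted("((A,B),(C,D));")
        h = dollo_reconstruct(tree, {"A": 1, "B": 0, "C": 1, "D": 0})
        assert h.gain_edge == frozenset("ABCD")
        assert annotate_losses(h) == ["B", "D"]
        assert h.n_losses == brute_force_min_losses(
            tree, {"A": 1, "B": 0, "C": 1, "D": 0}
        )

    def test_all_absent_is_an_error(self):
        with pytest.raises(ValidationError, match="all-absent"):
            dollo_reconstruct(rooted("((A,B),C);"), {"A": 0, "B": 0, "C": 0})

    def test_leaf_vector_mismatch_is_an_error(self):
        with pytest.raises(ValidationError, match="does not match"):
            dollo_reconstruct(rooted("((A,B),C);"), {"A": 1, "B": 1})


class TestDolloOptimality:
    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_matches_brute_force_on_all_vectors(self, n_leaves):
        for seed in range(4):
            tree = generate_random_tree(n_leaves, seed=seed)
            leaves = leaf_labels(tree)
            for bits in range(1, 2 ** n_leaves):
                presence = {
                    leaf: (bits >> k) & 1 for k, leaf in enumerate(leaves)
                }
                h = dollo_reconstruct(tree, presence)
                assert h.n_losses == brute_force_min_losses(tree, presence)
                for leaf in leaves:
                    assert h.implied_presence[frozenset({leaf})] == presence[leaf]

    def test_adding_a_present_leaf_never_moves_gain_toward_leaves(self):
        for seed in range(5):
            tree = generate_random_tree(6, seed=seed)
            leaves = leaf_labels(tree)
            presence = {l: 0 for l in leaves}
            presence[leaves[0]] = 1
            prev = dollo_reconstruct(tree, presence).gain_edge
            for leaf in leaves[1:]:
                presence[leaf] = 1
                gain = dollo_reconstruct(tree, presence).gain_edge
                assert prev <= gain  # gain clade only grows
                prev = gain


class TestSimulateRoundTrip:
    def test_root_gain_no_losses_is_all_ones(self):
        tree = rooted("((A,B),(C,D));")
        presence, _ = simulate_gainloss(tree, frozenset("ABCD"), [])
        assert all(presence.values())

    def test_cherry_gain_restricts_presence(self):
        tree = rooted("((A,B),(C,D));")
        presence, _ = simulate_gainloss(tree, frozenset("AB"), [])
        assert presence == {"A": 1, "B": 1, "C": 0, "D": 0}

    def test_leaf_loss_under_root_gain(self):
        tree = rooted("((A,B),(C,D));")
        presence, _ = simulate_gainloss(tree, frozenset("ABCD"), [frozenset("C")])
        assert presence == {"A": 1, "B": 1, "C": 0, "D": 1}

    def test_loss_above_gain_rejected(self):
        tree = rooted("((A,B),(C,D));")
        with pytest.raises(ValidationError, match="below"):
            simulate_gainloss(tree, frozenset("AB"), [frozenset("ABCD")])

    def test_reconstruction_recovers_unique_optima(self):
        for seed in range(10):
            tree = generate_random_tree(7, seed=seed)
            clades = sorted(set(clade_map(tree).values()), key=lambda c: -len(c))
            gain = clades[0]  # root clade
            # single-leaf losses on non-sister leaves are always recoverable
            leaves = sorted(gain)
            losses = [frozenset({leaves[0]})]
            presence, truth = simulate_gainloss(tree, gain, losses)
            h = dollo_reconstruct(tree, presence)
            if h.n_losses == len(losses):  # planted history is an optimum
                assert h.loss_edges == truth.payload["loss_edges"]


class TestMolluscFixture:
    def test_delta2_gain_and_three_gastropod_losses(self):
        matrix, truth = mollusc_presence_matrix()
        tree = mollusc_tree()
        presence = {sp: int(matrix.loc["Delta2", sp]) for sp in matrix.columns}
        h = dollo_reconstruct(tree, presence, family="Delta2")
        assert h.gain_edge == MOLLUSC_GAIN_CLADE
        assert h.loss_edges == MOLLUSC_DELTA2_LOSSES
        assert h.n_losses == 3
        assert not h.origin_at_root


class TestGainLossMatrix:
    def test_deeper_origin_ranks_first(self):
        tree = rooted("((A,B),(C,D));")
        matrix = pd.DataFrame(
            {"A": [1, 1], "B": [1, 1], "C": [1, 0], "D": [1, 0]},
            index=["old", "young"],
        )
        histories = gainloss_matrix(tree, matrix)
        assert [h.family for h in histories] == ["old", "young"]

    def test_species_mismatch_lists_difference(self):
        tree = rooted("((A,B),C);")
        matrix = pd.DataFrame({"A": [1], "B": [1], "X": [1]}, index=["f"])
        with pytest.raises(ValidationError, match="X"):
            gainloss_matrix(tree, matrix)

    def test_all_absent_families_are_skipped(self):
        tree = rooted("((A,B),C);")
        matrix = pd.DataFrame({"A": [0, 1], "B": [0, 1], "C": [0, 0]}, index=["f", "g"])
        histories = gainloss_matrix(tree, matrix)
        assert [h.family for h in histories] == ["g"]
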