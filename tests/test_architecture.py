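"""Family classification from domain architectures."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from notchevo.architecture import (
    ArchitectureSignature,
    GeneModel,
    build_presence_absence,
    classify_gene,
    count_domains,
    default_signatures,
    dsl_group,
    enumerate_dsl_instances,
    filter_hits,
    read_signatures,
    resolve_overlaps,
    write_signatures,
)
from notchevo.errors import AmbiguousClassificationError, ValidationError
from notchevo.io_formats import DomainHitRow, SequenceRecord
from notchevo.synthetic import (
    FAMILY_LABELS,
    add_decoy_domain,
    generate_gene_with_architecture,
)


def make_gene(hits_spec, gene_id="g", species="S", length=2000):
    hits = [
        DomainHitRow(gene_id, name, None, start, end, ev)
        for name, start, end, ev in hits_spec
    ]
    protein = SequenceRecord(gene_id, "", "A" * length, "protein")
    return GeneModel(gene_id, species, protein, hits=hits)


class TestFilterHits:
    def test_threshold_boundary(self):
        keep = DomainHitRow("g", "EGF", None, 1, 30, 1e-6)
        drop = DomainHitRow("g", "EGF", None, 40, 70, 1e-4)
        assert filter_hits([keep, drop], 1e-5) == [keep]

    def test_empty_input(self):
        assert filter_hits([], 1e-5) == []

    def test_agrees_with_direct_scan(self):
        rng = random.Random(0)
        hits = [
            DomainHitRow("g", "EGF", None, 1, 30, 10 ** rng.uniform(-12, 0))
            for _ in range(500)
        ]
        expected = [h for h in hits if h.e_value <= 1e-5]
        assert filter_hits(hits, 1e-5) == expected


class TestResolveOverlaps:
    def test_identical_intervals_keep_best_e_value(self):
        good = DomainHitRow("g", "DSL", None, 10, 60, 1e-10)
        bad = DomainHitRow("g", "EGF", None, 10, 60, 1e-3)
        assert resolve_overlaps([bad, good]) == [good]

    def test_disjoint_hits_all_retained(self):
        hits = [
            DomainHitRow("g", "EGF", None, 1, 30, 1e-6),
            DomainHitRow("g", "EGF", None, 40, 70, 1e-6),
        ]
        assert resolve_overlaps(hits) == hits

    def test_greedy_admission_is_consistent(self):
        # Independent characterisation of the greedy optimum: every dropped
        # hit must conflict with a kept hit of better (e, start, name) rank.
        rng = random.Random(1)
        for _ in range(50):
            hits = [
                DomainHitRow(
                    "g",
                    rng.choice("ABCDEF"),
                    None,
                    s := rng.randrange(1, 150),
                    s + rng.randrange(10, 60),
                    10 ** rng.uniform(-12, -1),
                )
                for _ in range(6)
            ]
            kept = resolve_overlaps(hits)
            rank = lambda h: (h.e_value, h.env_start, h.domain_name)

            def conflicts(a, b):
                ov = min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1
                return ov > 0.5 * min(a.length, b.length)

            for h in hits:
                if h in kept:
                    continue
                assert any(conflicts(h, k) and rank(k) < rank(h) for k in kept)
            for i, a in enumerate(kept):
                assert not any(conflicts(a, b) for b in kept[i + 1 :])


class TestClassifyGene:
    def test_delta_architecture(self):
        gene = make_gene(
            [("MNLL", 1, 30, 1e-9), ("DSL", 45, 90, 1e-12), ("EGF", 100, 130, 1e-8),
             ("EGF", 140, 170, 1e-8)]
        )
        assert classify_gene(gene).family == "Delta"

    def test_vwc_makes_jagged_win_by_specificity(self):
        gene = make_gene(
            [("MNLL", 1, 30, 1e-9), ("DSL", 45, 90, 1e-12), ("EGF", 100, 130, 1e-8),
             ("VWC", 200, 260, 1e-7)]
        )
        assert classify_gene(gene).family == "Jagged"

    def test_lone_dsl_is_delta_like(self):
        assert classify_gene(make_gene([("DSL", 10, 60, 1e-9)])).family == "Dll"

    def test_no_hits_unassigned(self):
        a = classify_gene(make_gene([]))
        assert a.family == "unassigned"

    def test_notch_requires_exactly_three_lnr(self):
        base = [("EGF", 1, 35, 1e-9), ("EGF", 40, 74, 1e-9), ("TM", 400, 422, 1e-6),
                ("ANK", 500, 532, 1e-9), ("ANK", 540, 572, 1e-9)]
        lnr3 = [("LNR", 100 + 40 * i, 130 + 40 * i, 1e-8) for i in range(3)]
        lnr4 = lnr3 + [("LNR", 260, 290, 1e-8)]
        assert classify_gene(make_gene(base + lnr3)).family == "Notch"
        assert classify_gene(make_gene(base + lnr4)).family == "unassigned"

    def test_equal_specificity_tie_is_an_error(self):
        sigs = [
            ArchitectureSignature("FamA", [("DSL", 1, None)]),
            ArchitectureSignature("FamB", [("DSL", 1, None)]),
        ]
        with pytest.raises(AmbiguousClassificationError, match="FamA.*FamB"):
            classify_gene(make_gene([("DSL", 10, 60, 1e-9)]), sigs)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_classification_invariant_to_hit_order(self, rnd):
        gene = make_gene(
            [("MNLL", 1, 30, 1e-9), ("DSL", 45, 90, 1e-12), ("EGF", 100, 130, 1e-8),
             ("VWC", 200, 260, 1e-7), ("EGF", 300, 330, 1e-8)]
        )
        shuffled = list(gene.hits)
        rnd.shuffle(shuffled)
        gene2 = GeneModel(gene.gene_id, gene.species_id, gene.protein, hits=shuffled)
        assert classify_gene(gene2).family == classify_gene(gene).family

    @pytest.mark.parametrize("family", FAMILY_LABELS)
    def test_planted_family_recovered_and_decoy_invariant(self, family):
        for seed in range(5):
            gene, truth = generate_gene_with_architecture(family, seed=seed)
            verdict = classify_gene(gene).family
            assert verdict == truth.payload["architecture_family"]
            decoyed = add_decoy_domain(gene, seed=seed)
            assert classify_gene(decoyed).family == verdict


class TestDslOperations:
    def test_multi_dsl_instances_are_ordered_by_start(self):
        gene = make_gene([("DSL", 100, 150, 1e-9), ("DSL", 10, 60, 1e-9)])
        assert enumerate_dsl_instances(gene) == ["g-1", "g-2"]

    def test_single_dsl_keeps_bare_id(self):
        assert enumerate_dsl_instances(make_gene([("DSL", 10, 60, 1e-9)])) == ["g"]

    def test_no_dsl_yields_empty(self):
        assert enumerate_dsl_instances(make_gene([("EGF", 10, 40, 1e-9)])) == []

    @pytest.mark.parametrize(
        "spec, expected",
        [
            ([("DSL", 10, 60, 1e-9)], "dsl_only"),
            ([("DSL", 10, 60, 1e-9), ("DSL", 70, 120, 1e-9), ("DSL", 130, 180, 1e-9)],
             "dsl_tandem"),
            ([("MNLL", 1, 30, 1e-9), ("DSL", 45, 90, 1e-9), ("EGF", 100, 130, 1e-8)],
             "dsl_egf"),
            ([("MNLL", 1, 30, 1e-9), ("DSL", 45, 90, 1e-9), ("EGF", 100, 130, 1e-8),
              ("VWC", 200, 260, 1e-7)], "dsl_egf_other"),
        ],
    )
    def test_four_group_partition(self, spec, expected):
        assert dsl_group(make_gene(spec)) == expected

    def test_group_requires_dsl(self):
        with pytest.raises(ValidationError):
            dsl_group(make_gene([("EGF", 10, 40, 1e-9)]))


class TestCountsAndPresence:
    def test_counts_are_additive_over_genes(self):
        g1 = make_gene([("EGF", 1, 35, 1e-9), ("EGF", 40, 74, 1e-9)], "g1")
        g2 = make_gene([("EGF", 1, 35, 1e-9), ("EGF", 40, 74, 1e-9)], "g2")
        table = count_domains([g1, g2], {"EGF"})
        assert table.loc[0, "count"] == 4

    def test_counts_match_hand_tally_on_random_set(self):
        rng = random.Random(3)
        genes, tally = [], {}
        for k in range(30):
            sp = f"S{rng.randrange(3)}"
            spec = [
                (rng.choice(["EGF", "DSL", "ANK"]), 1 + 100 * i, 40 + 100 * i, 1e-8)
                for i in range(rng.randrange(1, 5))
            ]
            genes.append(make_gene(spec, f"g{k}", sp))
            for name, *_ in spec:
                tally[(sp, name)] = tally.get((sp, name), 0) + 1
        table = count_domains(genes)
        got = {
            (r.species_id, r.domain_name): r.count for r in table.itertuples()
        }
        assert got == tally

    def test_presence_and_duplication_counts(self):
        a1 = classify_gene(make_gene([("DSL", 10, 60, 1e-9)], "g1"))
        a2 = classify_gene(make_gene([("DSL", 10, 60, 1e-9)], "g2"))
        presence, counts = build_presence_absence(
            [(a1, "S1"), (a2, "S1")], ["S1", "S2"], ["Dll", "Jagged"]
        )
        assert presence.loc["Dll", "S1"] == 1 and counts.loc["Dll", "S1"] == 2
        assert (presence.loc["Jagged"] == 0).all()

    def test_undeclared_species_is_error(self):
        a = classify_gene(make_gene([("DSL", 10, 60, 1e-9)]))
        with pytest.raises(ValidationError, match="species"):
            build_presence_absence([(a, "S9")], ["S1"], ["Dll"])


def test_signature_file_round_trip(tmp_path):
    sigs = default_signatures()
    p = tmp_path / "sig.tsv"
    write_signatures(sigs, p)
    assert read_signatures(p) == sigs
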