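import random

import pytest

import opucore as oc
from opucore.errors import ClassificationError, DelineationError, InputError

from _oracles import brute_force_partition, random_anchored_tree
from conftest import parse_tree


def _partition(opus):
    return {frozenset(o.members) for o in opus}


class TestDelineation:
    def test_single_query_sister_to_reference(self, simple_refs):
        opus = oc.delineate_opus(parse_tree("((q1,R1),(R2,R3));"), simple_refs)
        assert len(opus) == 1
        assert opus[0].members == ["q1"]
        assert opus[0].anchor_refs == ["R1"]

    def test_query_pair_anchored_at_root(self, simple_refs):
        opus = oc.delineate_opus(parse_tree("((q1,q2),R1);"), simple_refs[:1])
        assert len(opus) == 1
        assert opus[0].members == ["q1", "q2"]
        assert opus[0].anchor_refs == ["R1"]

    def test_nested_anchors_yield_distinct_opus(self, simple_refs):
        opus = oc.delineate_opus(parse_tree("(((q1,R1),q2),R2);"), simple_refs[:2])
        by_members = {tuple(o.members): o for o in opus}
        assert set(by_members) == {("q1",), ("q2",)}
        assert by_members[("q1",)].anchor_refs == ["R1"]
        assert by_members[("q2",)].anchor_refs == ["R1"]

    def test_no_reference_tips_is_an_error(self, simple_refs):
        with pytest.raises(DelineationError):
            oc.delineate_opus(parse_tree("((q1,q2),q3);"), simple_refs)

    def test_duplicate_tip_labels_rejected(self, simple_refs):
        import dendropy

        tree = parse_tree("((a,R1),(b,R2));")
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label in ("a", "b"):
                leaf.taxon = dendropy.Taxon("q1")
        with pytest.raises(InputError):
            oc.delineate_opus(tree, simple_refs)

    def test_matches_exhaustive_clade_oracle(self, simple_refs):
        """On random trees the ascent equals brute-force clade enumeration."""
        rng = random.Random(42)
        mk = oc.make_lineage
        for _ in range(300):
            newick, ref_ids = random_anchored_tree(rng)
            refs = [oc.ReferenceTaxon(r, mk("P", "C", "O", "F", "G", r), True) for r in ref_ids]
            opus = oc.delineate_opus(parse_tree(newick), refs)
            expected_partition, expected_anchors = brute_force_partition(newick, ref_ids)
            assert _partition(opus) == expected_partition
            for o in opus:
                assert frozenset(o.anchor_refs) == expected_anchors[frozenset(o.members)]

    def test_partition_covers_all_queries_disjointly(self, simple_refs):
        rng = random.Random(7)
        mk = oc.make_lineage
        for _ in range(50):
            newick, ref_ids = random_anchored_tree(rng)
            refs = [oc.ReferenceTaxon(r, mk("P", "C", "O", "F", "G", r), True) for r in ref_ids]
            tree = parse_tree(newick)
            queries = {lf.taxon.label for lf in tree.leaf_node_iter()} - set(ref_ids)
            opus = oc.delineate_opus(tree, refs)
            seen = [m for o in opus for m in o.members]
            assert sorted(seen) == sorted(set(seen))
            assert set(seen) == queries


def _opu(members=("q1",), anchor_refs=("R1",), representative="q1"):
    return oc.Opu("OPU0001", list(members), list(anchor_refs), representative=representative)


def _otus(identity, ref="R1", count=10):
    return {"q1": oc.OtuRecord("q1", count, {ref: identity})}


class TestClassification:
    @pytest.mark.parametrize(
        "identity, category, taxon",
        [
            (99.1, oc.OpuCategory.KNOWN_SPECIES, "S1"),
            (98.9, oc.OpuCategory.KNOWN_SPECIES, "S1"),
            (98.7, oc.OpuCategory.KNOWN_SPECIES, "S1"),  # equality goes to known
            (98.5, oc.OpuCategory.NEW_SPECIES, "G1"),
            (96.0, oc.OpuCategory.NEW_SPECIES, "G1"),
            (94.7, oc.OpuCategory.NEW_SPECIES, "G1"),
            (94.5, oc.OpuCategory.NEW_SPECIES, "G1"),  # equality goes to new species
        ],
    )
    def test_identity_thresholds(self, simple_refs, identity, category, taxon):
        opu = oc.classify_opu(_opu(), simple_refs, _otus(identity))
        assert (opu.category, opu.assigned_taxon) == (category, taxon)
        assert opu.best_identity == identity

    @pytest.mark.parametrize(
        "anchors, category, taxon",
        [
            (("R1", "R3"), oc.OpuCategory.UNCULTURED_GENUS, "F1"),  # share family only
            (("R1", "R2"), oc.OpuCategory.NEW_SPECIES, "G1"),  # shared genus overrides
        ],
    )
    def test_below_genus_threshold_uses_anchor_clade(self, simple_refs, anchors, category, taxon):
        opu = oc.classify_opu(_opu(anchor_refs=anchors), simple_refs, _otus(91.0))
        assert (opu.category, opu.assigned_taxon) == (category, taxon)
        assert opu.best_identity == 91.0

    @pytest.mark.parametrize(
        "lineages, category, taxon",
        [
            ([("P", "C", "O", "Fa", "Ga", "Sa"), ("P", "C", "O", "Fb", "Gb", "Sb")],
             oc.OpuCategory.UNCULTURED_FAMILY, "O"),
            ([("P", "C", "Oa", "Fa", "Ga", "Sa"), ("P", "C", "Ob", "Fb", "Gb", "Sb")],
             oc.OpuCategory.UNCULTURED_ORDER, "C"),
            ([("P", "Ca", "Oa", "Fa", "Ga", "Sa"), ("P", "Cb", "Ob", "Fb", "Gb", "Sb")],
             oc.OpuCategory.UNCULTURED_CLASS, "P"),
        ],
    )
    def test_uncultured_rank_ladder(self, lineages, category, taxon):
        refs = [
            oc.ReferenceTaxon(f"R{i}", oc.make_lineage(*lin), True)
            for i, lin in enumerate(lineages, start=1)
        ]
        opu = _opu(anchor_refs=[r.tip_id for r in refs])
        out = oc.classify_opu(opu, refs, _otus(90.0))
        assert (out.category, out.assigned_taxon) == (category, taxon)

    def test_non_type_strain_never_triggers_known_species(self, simple_refs):
        refs = [oc.ReferenceTaxon("R1", simple_refs[0].lineage, is_type_strain=False)]
        opu = oc.classify_opu(_opu(), refs, _otus(99.5))
        # identity to a non-type reference is ignored; clade evidence decides
        assert opu.category == oc.OpuCategory.NEW_SPECIES
        assert opu.best_identity is None

    def test_no_evidence_raises(self):
        opu = oc.Opu("OPU0001", ["q1"], [], representative="q1")
        with pytest.raises(ClassificationError):
            oc.classify_opu(opu, [], {"q1": oc.OtuRecord("q1", 1, {})})

    def test_raising_species_threshold_never_promotes_to_known(self, simple_refs):
        for identity in [90 + 0.05 * i for i in range(200)]:
            base = oc.classify_opu(_opu(), simple_refs, _otus(identity)).category
            strict = oc.classify_opu(
                _opu(), simple_refs, _otus(identity),
                oc.ThresholdConfig(species_identity=99.5),
            ).category
            if base == oc.OpuCategory.NEW_SPECIES:
                assert strict != oc.OpuCategory.KNOWN_SPECIES


class TestRepresentative:
    @pytest.mark.parametrize(
        "counts, winner",
        [({"q1": 50, "q2": 100}, "q2"), ({"q1": 10, "q2": 10}, "q1"), ({"q1": 3}, "q1")],
    )
    def test_most_frequent_wins_ties_lexicographic(self, counts, winner):
        otus = {q: oc.OtuRecord(q, c) for q, c in counts.items()}
        opu = oc.Opu("OPU0001", sorted(counts), ["R1"])
        assert oc.pick_representative(opu, otus) == winner
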