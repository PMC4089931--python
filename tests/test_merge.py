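"""Merge engine: minting, axiom translation, decision tree, homology."""

import re

import pytest

from anatomerge.align import MappingEntry
from anatomerge.fixtures import FixtureSpec, generate_fixture
from anatomerge.merge import (
    DEFAULT_RULES,
    CollisionError,
    DropRecord,
    HomologyAssertion,
    IDSpaceRule,
    MergeError,
    MergeValidationError,
    NovelIdAllocator,
    check_isomorphism,
    export_homology,
    mint_migrated_id,
    mint_novel_id,
    run_merge,
    translate_axiom,
    write_homology_table,
)
from anatomerge.model import (
    AxiomKind,
    ClassTerm,
    Definition,
    Identifier,
    Ontology,
    Synonym,
    is_a,
    relationship,
)


def ident(curie):
    return Identifier.parse(curie)


class TestMintMigratedId:
    @pytest.mark.parametrize("source,expected", [
        ("TAO:0001611", "UBERON:2001611"),
        ("AAO:0000680", "UBERON:3000680"),
        ("VSAO:0000093", "UBERON:4000093"),
    ])
    def test_lead_digits_plus_preserved_tail(self, source, expected):
        rule = DEFAULT_RULES[source.split(":")[0]]
        assert mint_migrated_id(ident(source), rule, set()).curie == expected

    def test_collision_rejected(self):
        existing = {ident("UBERON:2001611")}
        with pytest.raises(CollisionError):
            mint_migrated_id(ident("TAO:0001611"), DEFAULT_RULES["TAO"],
                             existing)

    def test_wrong_prefix_rejected(self):
        with pytest.raises(MergeError):
            mint_migrated_id(ident("AAO:0000680"), DEFAULT_RULES["TAO"], set())

    def test_rule_width_invariant(self):
        with pytest.raises(MergeError):
            IDSpaceRule("TAO", "2", 7)  # 1 + 7 != 7


class TestNovelIdAllocator:
    def test_counter_formats_into_42_space(self):
        alloc = NovelIdAllocator(next_counter=22)
        assert mint_novel_id(alloc, set()).curie == "UBERON:4200022"

    def test_fresh_allocator_starts_at_one(self):
        assert mint_novel_id(NovelIdAllocator(), set()).curie == "UBERON:4200001"

    def test_consecutive_calls_distinct_increasing(self):
        alloc = NovelIdAllocator()
        a = mint_novel_id(alloc, set())
        b = mint_novel_id(alloc, set())
        assert a != b and a.curie < b.curie

    def test_skips_collisions(self):
        alloc = NovelIdAllocator()
        taken = {ident("UBERON:4200001")}
        assert mint_novel_id(alloc, taken).curie == "UBERON:4200002"


class TestTranslateAxiom:
    MAPPING = {ident("TAO:0001611"): ident("UBERON:2001611"),
               ident("TAO:0000621"): ident("UBERON:0006597")}

    def test_part_of_rewritten_through_mapping(self):
        ax = relationship(ident("TAO:0001611"), "part_of", ident("TAO:0000621"))
        out = translate_axiom(ax, self.MAPPING)
        assert out.subject.curie == "UBERON:2001611"
        assert out.object.curie == "UBERON:0006597"
        assert out.property == "part_of"

    def test_unmapped_object_becomes_drop_record(self):
        ax = relationship(ident("TAO:0001611"), "part_of", ident("TAO:0009999"))
        out = translate_axiom(ax, self.MAPPING)
        assert isinstance(out, DropRecord)
        assert out.reason == "UNMAPPED_OBJECT"

    def test_identity_map_leaves_axiom_unchanged(self):
        ax = is_a(ident("TAO:0001611"), ident("TAO:0000621"))
        identity = {i: i for i in (ax.subject, ax.object)}
        assert translate_axiom(ax, identity) == ax


class TestCheckIsomorphism:
    def build(self, with_target_axiom):
        source = Ontology()
        source.add_class(ClassTerm(id=ident("TAO:0000621"), label="quadrate"))
        source.add_class(ClassTerm(id=ident("TAO:0001637"),
                                   label="quadrate-anguloarticular joint"))
        source.add_axiom(relationship(ident("TAO:0000621"), "overlaps",
                                      ident("TAO:0001637")))
        target = Ontology()
        target.add_class(ClassTerm(id=ident("UBERON:0006597"),
                                   label="quadrate bone"))
        target.add_class(ClassTerm(id=ident("UBERON:0011581"),
                                   label="quadrate-articular joint"))
        if with_target_axiom:
            target.add_axiom(relationship(ident("UBERON:0006597"), "overlaps",
                                          ident("UBERON:0011581")))
        mapping = {ident("TAO:0000621"): ident("UBERON:0006597"),
                   ident("TAO:0001637"): ident("UBERON:0011581")}
        return source, target, mapping

    def test_missing_overlaps_axiom_detected(self):
        source, target, mapping = self.build(with_target_axiom=False)
        missing = check_isomorphism(ident("TAO:0000621"),
                                    ident("UBERON:0006597"),
                                    mapping, source, target)
        assert len(missing) == 1
        assert missing[0].property == "overlaps"

    def test_identical_translated_sets_are_isomorphic(self):
        source, target, mapping = self.build(with_target_axiom=True)
        assert check_isomorphism(ident("TAO:0000621"),
                                 ident("UBERON:0006597"),
                                 mapping, source, target) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_set_difference_oracle(self, seed, small_fixture=None):
        src, tgt, entries, _ = generate_fixture(FixtureSpec(30, 12, seed=seed))
        mapping = {e.source_id: e.target_id for e in entries}
        for e in entries:
            missing = check_isomorphism(e.source_id, e.target_id, mapping,
                                        src, tgt)
            translated = {
                (int(a.kind), a.property or "",
                 mapping.get(a.object, a.object).curie)
                for a in src.axioms if a.subject == e.source_id}
            present = {(int(a.kind), a.property or "", a.object.curie)
                       for a in tgt.axioms if a.subject == e.target_id}
            assert {(int(m.kind), m.property or "", m.object.curie)
                    for m in missing} == translated - present


class TestRunMergeWorkedExample:
    def test_migration_pair(self, worked):
        source, target, entries = worked["migration_pair"]
        result = run_merge([source], target, entries, DEFAULT_RULES)
        # unmatched process migrates with preserved label and rewritten axiom
        minted = result.ext.get(ident("UBERON:2001611"))
        assert minted.label == "quadrate posterodorsolateral process"
        (ax,) = result.ext.axioms_about(minted.id)
        assert (ax.property, ax.object.curie) == ("part_of", "UBERON:0006597")
        # matched quadrate obsoleted with replaced_by the target class
        stub = result.stubs["TAO"].get(ident("TAO:0000621"))
        assert stub.is_obsolete
        assert [r.curie for r in stub.replaced_by] == ["UBERON:0006597"]
        # target carries the source definition as an external definition
        core_term = result.core.get(ident("UBERON:0006597"))
        assert any("palatoquadrate" in d.text
                   for d in core_term.external_definitions)
        assert ident("TAO:0000621") in core_term.xrefs

    def test_structured_comment_not_logical_axiom(self):
        source = Ontology()
        source.add_class(ClassTerm(id=ident("TAO:0000621"), label="quadrate"))
        source.add_class(ClassTerm(id=ident("TAO:0001637"),
                                   label="quadrate-anguloarticular joint"))
        source.add_axiom(relationship(ident("TAO:0000621"), "overlaps",
                                      ident("TAO:0001637")))
        target = Ontology()
        target.add_class(ClassTerm(id=ident("UBERON:0006597"),
                                   label="quadrate bone"))
        entries = [MappingEntry(source_id=ident("TAO:0000621"),
                                target_id=ident("UBERON:0006597"),
                                provenance="t")]
        result = run_merge([source], target, entries, DEFAULT_RULES)
        core_term = result.core.get(ident("UBERON:0006597"))
        merge_notes = [c for c in core_term.comments
                       if c.startswith("MERGE NOTE")]
        assert len(merge_notes) == 1
        assert "overlaps" in merge_notes[0]
        # the missing axiom was NOT asserted logically
        assert all(a.property != "overlaps"
                   for a in result.core.axioms_about(core_term.id))

    def test_synonym_transfer_is_idempotent(self):
        source = Ontology()
        source.add_class(ClassTerm(id=ident("TAO:0000621"), label="quadrate",
                                   synonyms=[Synonym("quadratum", "EXACT")]))
        target = Ontology()
        target.add_class(ClassTerm(id=ident("UBERON:0006597"),
                                   label="quadrate",
                                   synonyms=[Synonym("quadratum", "EXACT")]))
        entries = [MappingEntry(source_id=ident("TAO:0000621"),
                                target_id=ident("UBERON:0006597"),
                                provenance="t")]
        result = run_merge([source], target, entries, DEFAULT_RULES)
        texts = [s.text for s in result.core.get(ident("UBERON:0006597")).synonyms]
        assert texts.count("quadratum") == 1
        assert texts.count("quadrate") == 0  # label already on target

    def test_mutually_referencing_unmatched_pair(self):
        source = Ontology()
        a, b = ident("TAO:0000010"), ident("TAO:0000020")
        source.add_class(ClassTerm(id=a, label="alpha element"))
        source.add_class(ClassTerm(id=b, label="beta element"))
        source.add_axiom(relationship(a, "part_of", b))
        source.add_axiom(relationship(b, "develops_from", a))
        target = Ontology()
        target.add_class(ClassTerm(id=ident("UBERON:0000001"), label="root"))
        result = run_merge([source], target, [], DEFAULT_RULES)
        ma, mb = ident("UBERON:2000010"), ident("UBERON:2000020")
        assert ma in result.ext and mb in result.ext
        (ax_a,) = result.ext.axioms_about(ma)
        assert (ax_a.property, ax_a.object) == ("part_of", mb)
        (ax_b,) = result.ext.axioms_about(mb)
        assert (ax_b.property, ax_b.object) == ("develops_from", ma)


class TestRunMergeProperties:
    @pytest.mark.parametrize("n,m,prefix", [(60, 25, "TAO"), (45, 0, "AAO"),
                                            (30, 30, "VSAO")])
    def test_conservation_and_patterns(self, n, m, prefix):
        src, tgt, entries, _ = generate_fixture(
            FixtureSpec(n, m, source_prefix=prefix, seed=5,
                        planted_nonisomorphic=min(1, m)))
        result = run_merge([src], tgt, entries, DEFAULT_RULES)
        assert result.report.n_merged == m
        assert result.report.n_minted == n - m
        assert result.report.n_merged + result.report.n_minted == len(
            src.nonobsolete_ids())
        rule = DEFAULT_RULES[prefix]
        pat = re.compile(rule.lead_digits + r"\d{%d}" % rule.preserved_digits)
        for o in result.report.outcomes:
            if o.outcome == "MINTED_NEW":
                assert pat.fullmatch(o.result_id.local_id)

    def test_no_dangling_source_references(self, small_fixture):
        src, tgt, entries, _ = small_fixture
        result = run_merge([src], tgt, entries, DEFAULT_RULES)
        for onto in (result.core, result.ext):
            for ax in onto.axioms:
                assert ax.subject.prefix != "TAO"
                assert ax.object.prefix != "TAO"

    def test_obsolete_stubs_form(self, small_fixture):
        src, tgt, entries, _ = small_fixture
        result = run_merge([src], tgt, entries, DEFAULT_RULES)
        stubs = result.stubs["TAO"]
        assert len(stubs) == len(src.nonobsolete_ids())
        for term in stubs.terms():
            assert term.is_obsolete
            assert len(term.replaced_by) == 1
            assert stubs.axioms_about(term.id) == []

    def test_rerun_on_own_output_is_noop(self, small_fixture):
        src, tgt, entries, _ = small_fixture
        first = run_merge([src], tgt, entries, DEFAULT_RULES)
        second = run_merge([first.stubs["TAO"]], first.core, entries,
                           DEFAULT_RULES)
        assert second.report.n_skipped == len(src.nonobsolete_ids())
        assert second.report.n_merged == second.report.n_minted == 0

    def test_preobsolete_chain_preserved(self):
        source = Ontology()
        source.add_class(ClassTerm(id=ident("TAO:0000100"), label="old",
                                   is_obsolete=True,
                                   replaced_by=[ident("VSAO:0000005")]))
        source.add_class(ClassTerm(id=ident("TAO:0000200"), label="live"))
        target = Ontology()
        target.add_class(ClassTerm(id=ident("UBERON:0000001"), label="root"))
        result = run_merge([source], target, [], DEFAULT_RULES)
        assert result.report.n_skipped == 1
        stub = result.stubs["TAO"].get(ident("TAO:0000100"))
        assert [r.curie for r in stub.replaced_by] == ["VSAO:0000005"]

    def test_validation_failure_aborts(self):
        source = Ontology()
        source.add_class(ClassTerm(id=ident("TAO:0000621"), label="quadrate"))
        entries = [MappingEntry(source_id=ident("TAO:0000621"),
                                target_id=ident("UBERON:0006597"),
                                provenance="t")]
        with pytest.raises(MergeValidationError):
            run_merge([source], Ontology(), entries, DEFAULT_RULES)

    def test_empty_source_empty_report(self):
        result = run_merge([Ontology()], Ontology(), [], DEFAULT_RULES)
        assert result.report.outcomes == []


class TestExportHomology:
    LUNG = Identifier.parse("UBERON:0002048")
    SWIM = Identifier.parse("UBERON:0006860")

    def test_two_member_grouping_single_pair(self, worked):
        assertions = export_homology(worked["homology"], evidence="ECO:0000205")
        assert len(assertions) == 1
        (a,) = assertions
        assert {a.entity_a, a.entity_b} == {self.LUNG, self.SWIM}
        assert a.relation == "homologous_to"
        assert a.reference == "lung - swim bladder"

    def test_three_member_grouping_three_pairs(self):
        members = [ident(f"UBERON:000000{i}") for i in (1, 2, 3)]
        assertions = export_homology([("triple", members)])
        assert len(assertions) == 3

    def test_duplicate_members_deduplicated(self):
        assertions = export_homology([("dup", [self.LUNG, self.SWIM,
                                               self.LUNG])])
        assert len(assertions) == 1

    def test_under_two_members_rejected(self):
        with pytest.raises(MergeError):
            export_homology([("singleton", [self.LUNG])])

    def test_pairs_normalized(self):
        with pytest.raises(MergeError):
            HomologyAssertion(self.SWIM, self.LUNG)

    def test_table_round_trips_fields(self):
        assertions = export_homology([("lung - swim bladder",
                                       [self.SWIM, self.LUNG])], "ECO:0000205")
        table = write_homology_table(assertions)
        assert "UBERON:0002048\tUBERON:0006860\thomologous_to\tECO:0000205" \
            in table
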