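"""Release-gate QC checks."""

import pytest

from anatomerge.fixtures import FixtureSpec, generate_fixture
from anatomerge.merge import DEFAULT_RULES, run_merge
from anatomerge.model import ClassTerm, Identifier, Ontology, is_a, relationship
from anatomerge.obo import parse_obo
from anatomerge.qc import (
    ERROR,
    WARNING,
    check_labels_definitions,
    check_orphans,
    check_replaced_by,
    check_ssao_xrefs,
    repair_ssao_xrefs,
    run_all_checks,
    write_violation_report,
)


def ident(curie):
    return Identifier.parse(curie)


class TestLabelsDefinitions:
    def test_two_labels_is_error(self):
        onto = parse_obo("format-version: 1.2\n\n[Term]\nid: TAO:0000001\n"
                         "name: first\nname: second\n")
        violations = check_labels_definitions(onto)
        assert [v.severity for v in violations] == [ERROR]
        assert "2 labels" in violations[0].message

    def test_two_definitions_is_error(self):
        onto = parse_obo('format-version: 1.2\n\n[Term]\nid: TAO:0000001\n'
                         'name: a\ndef: "one." []\ndef: "two." []\n')
        violations = check_labels_definitions(onto)
        assert [v.severity for v in violations] == [ERROR]

    def test_missing_label_is_error(self):
        onto = Ontology()
        onto.add_class(ClassTerm(id=ident("TAO:0000001"), label="x"))
        onto.get(ident("TAO:0000001")).label = None  # post-hoc corruption
        assert [v.severity for v in check_labels_definitions(onto)] == [ERROR]

    def test_obsolete_class_without_label_exempt(self):
        onto = Ontology()
        onto.add_class(ClassTerm(id=ident("TAO:0000001"), is_obsolete=True))
        assert check_labels_definitions(onto) == []

    def test_clean_fixture_empty(self):
        src, tgt, _, _ = generate_fixture(FixtureSpec(40, 10, seed=8))
        assert check_labels_definitions(src) == []
        assert check_labels_definitions(tgt) == []


def stub(curie, replaced_by=None, obsolete=True):
    return ClassTerm(id=ident(curie), is_obsolete=obsolete,
                     replaced_by=[ident(replaced_by)] if replaced_by else [])


class TestReplacedBy:
    def test_live_replacement_no_violation(self):
        onto = Ontology()
        onto.add_class(stub("TAO:0000001", "UBERON:2000001"))
        onto.add_class(ClassTerm(id=ident("UBERON:2000001"), label="ok"))
        assert check_replaced_by([onto]) == []

    def test_chain_warns_with_terminal_suggested(self):
        """A class replaced via another obsolete stub suggests the chain end."""
        tao = Ontology()
        tao.add_class(stub("TAO:0000001", "VSAO:0000001"))
        vsao = Ontology()
        vsao.add_class(stub("VSAO:0000001", "UBERON:2001611"))
        uberon = Ontology()
        uberon.add_class(ClassTerm(id=ident("UBERON:2001611"), label="end"))
        (v,) = check_replaced_by([tao, vsao, uberon])
        assert v.severity == WARNING
        assert v.suggested_fix == ident("UBERON:2001611")

    def test_undeclared_target_is_error(self):
        onto = Ontology()
        onto.add_class(stub("TAO:0000001", "UBERON:9999999"))
        (v,) = check_replaced_by([onto])
        assert v.severity == ERROR

    def test_cycle_is_error(self):
        onto = Ontology()
        onto.add_class(stub("TAO:0000001", "TAO:0000002"))
        onto.add_class(stub("TAO:0000002", "TAO:0000001"))
        violations = check_replaced_by([onto])
        assert violations and all(v.severity == ERROR for v in violations)


class TestSsaoXrefs:
    def merged_stub_set(self):
        onto = Ontology()
        onto.add_class(stub("TAO:0001611", "UBERON:2001611"))
        onto.add_class(ClassTerm(id=ident("TAO:0000700"), label="not merged"))
        return onto

    def ssao_with_xref(self, curie):
        zfa = Ontology()
        zfa.add_class(ClassTerm(id=ident("ZFA:0000001"), label="zf process",
                                xrefs=[ident(curie)]))
        return zfa

    def test_replaced_stub_warns_with_replacement(self):
        violations = check_ssao_xrefs(self.ssao_with_xref("TAO:0001611"),
                                      [self.merged_stub_set()])
        (v,) = violations
        assert v.severity == WARNING
        assert v.suggested_fix == ident("UBERON:2001611")

    def test_unknown_target_is_error(self):
        (v,) = check_ssao_xrefs(self.ssao_with_xref("TAO:0009999"),
                                [self.merged_stub_set()])
        assert v.severity == ERROR

    def test_unmerged_live_class_is_error(self):
        (v,) = check_ssao_xrefs(self.ssao_with_xref("TAO:0000700"),
                                [self.merged_stub_set()])
        assert v.severity == ERROR
        assert "never obsoleted" in v.message

    def test_xref_outside_merged_namespaces_ignored(self):
        violations = check_ssao_xrefs(self.ssao_with_xref("UBERON:2001611"),
                                      [self.merged_stub_set()])
        assert violations == []

    def test_repair_rewires_xref(self):
        ssao = self.ssao_with_xref("TAO:0001611")
        violations = check_ssao_xrefs(ssao, [self.merged_stub_set()])
        fixed = repair_ssao_xrefs(ssao, violations)
        assert fixed.get(ident("ZFA:0000001")).xrefs == [
            ident("UBERON:2001611")]
        # original untouched (checks are pure)
        assert ssao.get(ident("ZFA:0000001")).xrefs == [ident("TAO:0001611")]


class TestOrphans:
    ROOT = "AAO:0000000"

    def build(self):
        onto = Ontology()
        onto.add_class(ClassTerm(id=ident(self.ROOT),
                                 label="anatomical entity"))
        return onto

    def test_class_only_under_root_warned(self):
        onto = self.build()
        onto.add_class(ClassTerm(id=ident("AAO:3010205"), label="postminimus"))
        onto.add_axiom(is_a(ident("AAO:3010205"), ident(self.ROOT)))
        (v,) = check_orphans(onto, [ident(self.ROOT)])
        assert v.severity == WARNING
        assert v.subject == ident("AAO:3010205")

    def test_fully_placed_class_clean(self):
        onto = self.build()
        onto.add_class(ClassTerm(id=ident("AAO:0007844"),
                                 label="cartilage element"))
        onto.add_axiom(is_a(ident("AAO:0007844"), ident(self.ROOT)))
        onto.add_class(ClassTerm(id=ident("AAO:3010205"), label="postminimus"))
        onto.add_axiom(is_a(ident("AAO:3010205"), ident("AAO:0007844")))
        onto.add_axiom(relationship(ident("AAO:3010205"), "part_of",
                                    ident("AAO:0007844")))
        violations = check_orphans(onto, [ident(self.ROOT)])
        assert [v.subject for v in violations] == [ident("AAO:0007844")]

    def test_parentless_class_warned(self):
        onto = self.build()
        onto.add_class(ClassTerm(id=ident("AAO:0000655"),
                                 label="processus dorsalis"))
        (v,) = check_orphans(onto, [ident(self.ROOT)])
        assert "no is_a/part_of parent" in v.message

    @pytest.mark.parametrize("planted", [1, 3, 6])
    def test_planted_orphan_count_recovered(self, planted):
        src, _, _, truth = generate_fixture(
            FixtureSpec(40, 10, planted_orphans=planted, seed=13))
        violations = check_orphans(src, truth.root_ids)
        assert len(violations) == planted
        assert {v.subject for v in violations} == set(truth.orphan_ids)


class TestEndToEnd:
    def test_merge_output_has_zero_errors(self, small_fixture):
        src, tgt, entries, _ = small_fixture
        result = run_merge([src], tgt, entries, DEFAULT_RULES)
        ontos = [result.core, result.ext] + list(result.stubs.values())
        violations = run_all_checks(ontos)
        assert [v for v in violations if v.severity == ERROR] == []

    def test_report_format_and_fix_column(self):
        onto = Ontology()
        onto.add_class(stub("TAO:0000001", "TAO:0000002"))
        onto.add_class(stub("TAO:0000002", "UBERON:2000002"))
        onto.add_class(ClassTerm(id=ident("UBERON:2000002"), label="end"))
        text = write_violation_report(check_replaced_by([onto]))
        assert text.startswith("check_id\tsubject\tseverity\t")
        assert "UBERON:2000002" in text
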