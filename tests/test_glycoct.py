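"""GlycoCT condensed parsing and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glycantree as gt
from glycantree.glycoct import RawBase, RawLinkage, RawStructure, RawSubstituent
from glycantree.util import UNKNOWN

from conftest import GLCNAC_ONELINE, LEWIS_B, THREE_UND


class TestParse:
    def test_composed_glcnac_sections(self):
        raw = gt.parse_glycoct(GLCNAC_ONELINE)
        assert len(raw.res_entries) == 2 and len(raw.lin_entries) == 1
        base, sub = raw.res_entries
        assert isinstance(base, RawBase)
        assert (base.anomer, base.superclass, base.ring) == ("x", "HEX", (1, 5))
        assert base.config_stem == (("d", "glc"),)
        assert base.name == "dglc-HEX"
        assert isinstance(sub, RawSubstituent) and sub.name == "n-acetyl"
        (lin,) = raw.lin_entries
        assert (lin.parent_index, lin.child_index) == (1, 2)
        assert (lin.parent_bond, lin.child_bond) == ("d", "n")
        assert lin.parent_positions == frozenset({2})
        assert lin.child_positions == frozenset({1})
        assert raw.und_blocks == ()

    def test_single_residue_structure(self):
        raw = gt.parse_glycoct("RES\n1b:b-dgal-HEX-1:5")
        assert len(raw.res_entries) == 1 and not raw.lin_entries

    def test_repeat_sections_rejected(self):
        text = "RES\n1b:b-dglc-HEX-1:5\nREP\nREP1:2o(4+1)2d=1-4\n"
        with pytest.raises(gt.UnsupportedSection):
            gt.parse_glycoct(text)

    def test_unknown_position_token(self):
        raw = gt.parse_glycoct(
            "RES\n1b:b-dgal-HEX-1:5\n2b:a-lgal-HEX-1:5|6:d\nLIN\n1:1o(-1+1)2d"
        )
        (lin,) = raw.lin_entries
        assert lin.parent_positions == frozenset({UNKNOWN})
        assert lin.child_positions == frozenset({1})

    def test_alternative_positions(self):
        raw = gt.parse_glycoct(
            "RES\n1b:b-dgal-HEX-1:5\n2b:a-lgal-HEX-1:5|6:d\nLIN\n1:1o(3|6+1)2d"
        )
        assert raw.lin_entries[0].parent_positions == frozenset({3, 6})

    # hand-written dialect cases frozen as an independent reference for the
    # condensed grammar's corner tokens
    @pytest.mark.parametrize(
        "text, check",
        [
            ("RES\n1b:a-dman-HEX-1:5", lambda r: r.res_entries[0].name == "dman-HEX"),
            ("RES\n1b:o-dglc-HEX-0:0", lambda r: r.res_entries[0].anomer == "o"),
            ("RES\n1b:x-dglc-HEX-x:x", lambda r: r.res_entries[0].ring == (UNKNOWN, UNKNOWN)),
            (
                "RES\n1b:a-dgro-dgal-NON-2:6|1:a|2:keto|3:d",
                lambda r: r.res_entries[0].name == "dgro-dgal-NON"
                and r.res_entries[0].modifications == frozenset({(1, "a"), (2, "keto"), (3, "d")}),
            ),
            ("RES\n1b:b-dxyl-PEN-1:5", lambda r: r.res_entries[0].superclass == "PEN"),
            (
                "RES\n1b:b-dgal-HEX-1:5\n2s:sulfate\nLIN\n1:1o(3+1)2n",
                lambda r: r.lin_entries[0].child_bond == "n",
            ),
            (
                "RES\n1b:b-dgal-HEX-1:5\n2b:b-dglc-HEX-1:5\nLIN\n1:1o(-1+-1)2d",
                lambda r: r.lin_entries[0].child_positions == frozenset({UNKNOWN}),
            ),
            (
                "RES\n1b:b-dglc-HEX-1:5|6:d|4:d",
                lambda r: r.res_entries[0].modifications == frozenset({(4, "d"), (6, "d")}),
            ),
        ],
    )
    def test_dialect_corner_cases(self, text, check):
        assert check(gt.parse_glycoct(text))

    def test_dangling_index(self):
        with pytest.raises(gt.DanglingIndex):
            gt.parse_glycoct("RES\n1b:b-dgal-HEX-1:5\nLIN\n1:1o(3+1)99d")

    def test_cycle_detected(self):
        text = (
            "RES\n1b:b-dgal-HEX-1:5\n2b:b-dglc-HEX-1:5\n"
            "LIN\n1:1o(3+1)2d\n2:2o(3+1)1d"
        )
        with pytest.raises(gt.CyclicStructure):
            gt.parse_glycoct(text)

    def test_two_parents_rejected(self):
        text = (
            "RES\n1b:b-dgal-HEX-1:5\n2b:b-dglc-HEX-1:5\n3b:b-dman-HEX-1:5\n"
            "LIN\n1:1o(3+1)3d\n2:2o(3+1)3d"
        )
        with pytest.raises(gt.CyclicStructure):
            gt.parse_glycoct(text)

    def test_und_blocks(self):
        raw = gt.parse_glycoct(THREE_UND)
        assert len(raw.und_blocks) == 3
        blk = raw.und_blocks[0]
        assert blk.ordinal == 1 and blk.parent_candidate_ids == frozenset({1})
        assert blk.subtree_linkage is not None
        assert blk.subtree_linkage.parent_positions == frozenset({UNKNOWN})
        assert (blk.major_weight, blk.minor_weight) == (100.0, 100.0)

    def test_index_renumbering_is_isomorphic(self, rules):
        # same Lewis B structure with every RES index shifted by 10
        shifted = (
            "RES\n11b:b-dglc-HEX-1:5\n12s:n-acetyl\n13b:b-dgal-HEX-1:5\n"
            "14b:a-lgal-HEX-1:5|6:d\n15b:a-lgal-HEX-1:5|6:d\nLIN\n"
            "1:11d(2+1)12n\n2:11o(3+1)13d\n3:13o(2+1)14d\n4:11o(4+1)15d"
        )
        a = gt.build_glycan(gt.parse_glycoct(LEWIS_B), rules)
        b = gt.build_glycan(gt.parse_glycoct(shifted), rules)
        assert gt.isomorphic(a, b)


class TestSerialize:
    def test_worked_example_token_roundtrip(self):
        raw = gt.parse_glycoct(GLCNAC_ONELINE)
        assert gt.serialize_glycoct(raw).split("\n") == GLCNAC_ONELINE.split(" ")

    def test_empty_structure_invalid(self):
        with pytest.raises(gt.InvalidRaw):
            gt.serialize_glycoct(RawStructure((), (), ()))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_isomorphism(self, seed):
        rules = gt.default_rules()
        params = gt.GeneratorParams(seed=0)
        g, text, _ = gt.random_glycan(params, seed=seed, structure_id="rt")
        raw = gt.parse_glycoct(text)
        again = gt.parse_glycoct(gt.serialize_glycoct(raw))
        assert gt.isomorphic(
            gt.build_glycan(raw, rules, "rt"), gt.build_glycan(again, rules, "rt")
        )


class TestValidate:
    def test_worked_example_clean(self):
        assert gt.validate_glycoct(GLCNAC_ONELINE) == []

    def test_malformed_line_reported_with_line_number(self):
        issues = gt.validate_glycoct("RES\n1b:zzz")
        assert len(issues) == 1
        assert issues[0].severity == "error" and issues[0].line == 2

    def test_dangling_index_reported_not_raised(self):
        issues = gt.validate_glycoct("RES\n1b:b-dgal-HEX-1:5\nLIN\n1:1o(3+1)99d")
        assert len(issues) == 1 and "99" in issues[0].message


class TestCorpusContainer:
    def test_corpus_roundtrip(self, tmp_path, small_corpus, rules):
        records = [(g.id, text) for g, text, _ in small_corpus[:20]]
        path = tmp_path / "corpus.tsv"
        gt.write_corpus(path, records)
        back = gt.read_corpus(path)
        assert [sid for sid, _ in back] == [sid for sid, _ in records]
        for (sid, text), (_, text2) in zip(records, back):
            a = gt.build_glycan(gt.parse_glycoct(text), rules, sid)
            b = gt.build_glycan(gt.parse_glycoct(text2), rules, sid)
            assert gt.isomorphic(a, b)
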