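"""Pattern compilation, strict/fuzzy matching, bag search, chains, catalogs."""

import itertools

import numpy as np
import pytest

import glycantree as gt
from glycantree.query import (
    BASETYPE,
    COMPOSITION,
    compile_pattern,
    library_pattern,
)

from conftest import DISIALYL_CORE1, THREE_UND, build, random_query_pattern


class TestCompile:
    def test_fuzzy_lewis_probe_tree(self, rules):
        pat = compile_pattern("Gal[Fuc]GlcNAc[Fuc]", rules)
        root = pat.root
        assert pat.size == 4
        assert root.constraint.level == BASETYPE and root.constraint.name == "dglc-HEX"
        assert root.constraint.substituent == ("required", "n-acetyl")
        kids = sorted(
            (c.constraint.level, c.constraint.name, len(c.children)) for _, c in root.children
        )
        assert kids == [(BASETYPE, "dgal-HEX", 1), (COMPOSITION, "dHex", 0)]
        # all edges unconstrained
        for node in root.walk():
            for edge, _ in node.children:
                assert edge.parent_positions is None and edge.child_positions is None

    def test_lewis_y_fully_constrained(self, rules):
        pat = compile_pattern("Fuc(a1-2)Gal(b1-4)[Fuc(a1-3)]GlcNAc", rules)
        assert pat.size == 4
        by_parent_pos = {
            tuple(sorted(e.parent_positions)): c for e, c in pat.root.children
        }
        assert set(by_parent_pos) == {(3,), (4,)}
        gal = by_parent_pos[(4,)]
        assert gal.constraint.anomer == "b" and len(gal.children) == 1
        fuc_on_gal_edge, fuc_on_gal = gal.children[0]
        assert fuc_on_gal.constraint.anomer == "a"
        assert fuc_on_gal_edge.parent_positions == frozenset({2})

    def test_single_composition_node(self, rules):
        pat = compile_pattern("Hex", rules)
        assert pat.size == 1
        assert pat.root.constraint.level == COMPOSITION and pat.root.constraint.name == "Hex"

    def test_unknown_token(self, rules):
        with pytest.raises(gt.UnknownToken):
            compile_pattern("NotASugar", rules)

    def test_unbalanced_brackets(self, rules):
        with pytest.raises(gt.UnbalancedBracket):
            compile_pattern("Gal[Fuc", rules)
        with pytest.raises(gt.UnbalancedBracket):
            compile_pattern("Gal]Fuc", rules)

    def test_hex_matches_all_hexoses(self, rules):
        pat = compile_pattern("Hex", rules, ambiguity="strict")
        for text in ("RES\n1b:b-dgal-HEX-1:5", "RES\n1b:b-dglc-HEX-1:5", "RES\n1b:a-dman-HEX-1:5"):
            assert gt.match(pat, build(text, rules))


class TestMatch:
    def test_fuzzy_probe_finds_all_lewis_types(self, rules, lewis):
        pat = library_pattern("lewis_core_fuzzy", rules, ambiguity="fuzzy")
        # B and Y carry two fucoses and match; blanked B still matches
        for key in ("b", "y", "b_blanked"):
            assert gt.match(pat, lewis[key]), key
        # A and X carry a single fucose: the two-fucose probe must not fire
        for key in ("a", "x"):
            assert not gt.match(pat, lewis[key]), key
        mono = library_pattern("lewis_mono_fuzzy", rules, ambiguity="fuzzy")
        for key in ("a", "x", "b", "y"):
            assert gt.match(mono, lewis[key]), key

    def test_strict_misses_blanked_linkages(self, rules, lewis):
        strict_b = library_pattern("lewis_b", rules, ambiguity="strict")
        assert gt.match(strict_b, lewis["b"])
        assert not gt.match(strict_b, lewis["b_blanked"])
        fuzzy_b = library_pattern("lewis_b", rules, ambiguity="fuzzy")
        assert gt.match(fuzzy_b, lewis["b_blanked"])

    def test_strict_lewis_y_rejects_lewis_a(self, rules, lewis):
        pat = library_pattern("lewis_y", rules, ambiguity="strict")
        assert not gt.match(pat, lewis["a"])
        assert gt.brute_force_match(pat, lewis["a"]) == []

    def test_named_mismatch_never_fuzzy_matches(self, rules):
        # fuzziness is about missing knowledge: Gal never matches a Glc datum
        pat = compile_pattern("Gal", rules, ambiguity="fuzzy")
        assert not gt.match(pat, build("RES\n1b:b-dglc-HEX-1:5", rules))
        # ...but an unknown skeleton satisfies it in fuzzy mode only
        unknown = build("RES\n1b:x-xgal-HEX-1:5", rules)
        assert gt.match(pat, unknown)
        assert not gt.match(compile_pattern("Gal", rules, ambiguity="strict"), unknown)

    def test_root_anchor(self, rules):
        fuc_root = build("RES\n1b:a-lgal-HEX-1:5|6:d\n2b:b-dgal-HEX-1:5\nLIN\n1:1o(2+1)2d", rules)
        gal_root = build("RES\n1b:b-dgal-HEX-1:5\n2b:a-lgal-HEX-1:5|6:d\nLIN\n1:1o(2+1)2d", rules)
        pat = compile_pattern("Fuc", rules, anchor="root", ambiguity="strict")
        assert len(gt.match(pat, fuc_root)) == 1
        assert not gt.match(pat, gal_root)
        assert gt.match(pat.with_options(anchor="anywhere"), gal_root)

    def test_alternative_positions_membership(self, rules):
        data = build(
            "RES\n1b:b-dgal-HEX-1:5\n2b:b-dglc-HEX-1:5\nLIN\n1:1o(3|6+1)2d", rules
        )
        hit = compile_pattern("Glc(b1-3)Gal", rules, ambiguity="strict")
        miss = compile_pattern("Glc(b1-4)Gal", rules, ambiguity="strict")
        assert gt.match(hit, data)
        assert not gt.match(miss, data)

    def test_pattern_cannot_span_core_and_bag(self, rules):
        g = build(THREE_UND, rules)
        # GlcNAc core + Fuc bag item exist, but no tree holds both
        pat = compile_pattern("Fuc(a1-3)GlcNAc", rules, ambiguity="fuzzy", scope="both")
        assert not gt.match(pat, g)

    def test_whole_anchor_counts_automorphisms(self, rules):
        # symmetric tree: root with two identical Gal children
        sym = build(
            "RES\n1b:b-dglc-HEX-1:5\n2b:b-dgal-HEX-1:5\n3b:b-dgal-HEX-1:5\n"
            "LIN\n1:1o(3+1)2d\n2:1o(4+1)3d",
            rules,
        )
        pat = compile_pattern("Gal(1-?)[Gal(1-?)]Glc", rules, anchor="whole", ambiguity="fuzzy")
        matches = gt.match(pat, sym)
        assert len(matches) == 2  # the two branch assignments
        assert gt.brute_force_match(pat, sym) == matches


class TestOracleEquivalence:
    def test_match_equals_brute_force_on_random_pairs(self, rules, small_corpus):
        rng = np.random.default_rng(77)
        glycans = [g for g, _, _ in small_corpus if len(gt.residues(g, "both")) <= 12]
        checked = 0
        for i in range(150):
            g = glycans[int(rng.integers(len(glycans)))]
            pat = random_query_pattern(rng)
            assert gt.match(pat, g) == gt.brute_force_match(pat, g)
            checked += 1
        assert checked == 150

    def test_brute_force_guard(self, rules):
        params = gt.GeneratorParams(seed=0, residue_range=(13, 14))
        g, _, _ = gt.random_glycan(params, seed=1)
        with pytest.raises(gt.TooLarge):
            gt.brute_force_match(compile_pattern("Hex", rules), g)

    def test_unconstrained_single_node_matches_every_residue(self, rules, small_corpus):
        from glycantree.query import PatternNode

        pat = gt.QueryPattern(
            PatternNode(1, gt.NodeConstraint()),
            anchor="anywhere", ambiguity="fuzzy", scope="both",
        )
        for g, _, _ in small_corpus[:10]:
            assert len(gt.match(pat, g)) == len(gt.residues(g, "both"))


class TestMonotonicity:
    def test_strict_subset_fuzzy_and_anchor_nesting(self, rules, small_corpus):
        glycans = [g for g, _, _ in small_corpus]
        rng = np.random.default_rng(11)
        for _ in range(25):
            pat = random_query_pattern(rng, scope="both")
            strict_ids = {g.id for g in glycans if gt.match(pat.with_options(ambiguity="strict"), g)}
            fuzzy_ids = {g.id for g in glycans if gt.match(pat.with_options(ambiguity="fuzzy"), g)}
            assert strict_ids <= fuzzy_ids
            whole = {g.id for g in glycans if gt.match(pat.with_options(anchor="whole"), g)}
            root = {g.id for g in glycans if gt.match(pat.with_options(anchor="root"), g)}
            anywhere = {g.id for g in glycans if gt.match(pat.with_options(anchor="anywhere"), g)}
            assert whole <= root <= anywhere


class TestBagMultiset:
    def test_free_fuc_and_glcnac(self, rules):
        text = (
            "RES\n1b:b-dglc-HEX-1:5\n2s:n-acetyl\nLIN\n1:1d(2+1)2n\n"
            "UND\nUND1:100.0:100.0\nSubtreeLinkageID1:o(-1+1)d\nRES\n3b:a-lgal-HEX-1:5|6:d\n"
            "UND2:100.0:100.0\nSubtreeLinkageID1:o(-1+1)d\nRES\n4b:b-dgal-HEX-1:5\n"
            "UND3:100.0:100.0\nSubtreeLinkageID1:o(-1+1)d\nRES\n5b:b-dglc-HEX-1:5\n6s:n-acetyl\nLIN\n1:5d(2+1)6n"
        )
        g = build(text, rules)
        fuc = compile_pattern("Fuc", rules, scope="bag")
        glcnac = compile_pattern("GlcNAc", rules, scope="bag")
        assert gt.match_bag_multiset([fuc, glcnac], g)
        # distinctness: two Fuc patterns need two Fuc-matching items
        assert not gt.match_bag_multiset([fuc, fuc], g)

    def test_core_only_residues_do_not_count(self, rules, lewis):
        # Lewis B has Fuc and GlcNAc in the core but an empty bag
        fuc = compile_pattern("Fuc", rules, scope="bag")
        glcnac = compile_pattern("GlcNAc", rules, scope="bag")
        assert not gt.match_bag_multiset([fuc, glcnac], lewis["b"])

    def test_agreement_with_assignment_enumeration(self, rules, small_corpus):
        fuc = compile_pattern("Fuc", rules, scope="bag")
        glcnac = compile_pattern("GlcNAc", rules, scope="bag")
        hex_ = compile_pattern("Hex", rules, scope="bag")
        pattern_sets = [[fuc], [fuc, glcnac], [fuc, fuc], [hex_, hex_], [glcnac, hex_]]
        for g, _, _ in small_corpus[:60]:
            items = list(g.bag.items) if g.bag else []
            for pats in pattern_sets:
                # independent enumeration over item permutations
                expected = False
                for perm in itertools.permutations(range(len(items)), len(pats)):
                    ok = True
                    for p, j in zip(pats, perm):
                        probe = gt.Glycan(g.id, None, gt.GlycanBag([items[j]]))
                        if not gt.match(p, probe):
                            ok = False
                            break
                    if ok:
                        expected = True
                        break
                assert gt.match_bag_multiset(pats, g) == expected


class TestChainSearch:
    def test_disialyl_chain(self, rules):
        g = build(DISIALYL_CORE1, rules)
        sial = gt.NodeConstraint(COMPOSITION, "Neu5Ac")
        hits = gt.chain_search(sial, 2, g)
        assert len(hits) == 1 and len(hits[0].mapping) == 2

    def test_k1_reduces_to_node_match(self, rules, small_corpus):
        hexc = gt.NodeConstraint(COMPOSITION, "Hex")
        from glycantree.query import PatternNode

        single = gt.QueryPattern(PatternNode(1, hexc), anchor="anywhere", ambiguity="strict")
        for g, _, _ in small_corpus[:20]:
            # maximal chains of length ≥ 1 jointly cover exactly the
            # residues a single-node pattern matches
            chain_res = {rid for m in gt.chain_search(hexc, 1, g) for _, rid in m.mapping}
            node_res = {m.mapping[0][1] for m in gt.match(single, g)}
            assert chain_res == node_res

    def test_conjunction_with_core1(self, rules):
        g = build(DISIALYL_CORE1, rules)
        sial = gt.NodeConstraint(COMPOSITION, "Neu5Ac")
        core1 = library_pattern("o_core1", rules, anchor="root", ambiguity="strict", scope="core")
        assert gt.chain_search(sial, 2, g) and gt.match(core1, g)


class TestCatalog:
    def test_suffix_sum_identity(self, small_corpus):
        corpus = [g for g, _, _ in small_corpus]
        at_least = gt.run_catalog_query(11, corpus)
        exactly = gt.run_catalog_query(12, corpus)
        assert at_least == [sum(exactly[k:]) for k in range(9)]
        assert sum(exactly) == sum(1 for g in corpus if gt.bag_item_count(g) > 0)

    def test_no_substituent_roots_counts_zero(self, small_corpus):
        corpus = [g for g, _, _ in small_corpus]
        # generator roots are always monosaccharides, so query 1 is 0
        assert gt.run_catalog_query(1, corpus) == 0

    def test_substituent_only_root_counted(self, rules):
        g = build(
            "RES\n1s:phosphate\n2b:b-dglc-HEX-1:5\nLIN\n1:1n(1+6)2o", rules
        )
        assert gt.run_catalog_query(1, [g]) == 1

    def test_structure_census_queries(self, rules, small_corpus):
        corpus = [g for g, _, _ in small_corpus] + [gt.Glycan(id="idonly")]
        n = len(corpus)
        assert gt.run_catalog_query(14, corpus) == n
        assert gt.run_catalog_query(15, corpus) == n - 1
        assert gt.run_catalog_query(16, corpus) == n - 1
        assert gt.run_catalog_query(13, corpus) == 1
        assert gt.run_catalog_query(2, corpus) == gt.run_catalog_query(16, corpus)

    def test_q1_whole_core_n_glycan(self, rules):
        n_core = (
            "RES\n1b:b-dglc-HEX-1:5\n2s:n-acetyl\n3b:b-dglc-HEX-1:5\n4s:n-acetyl\n"
            "5b:b-dman-HEX-1:5\n6b:a-dman-HEX-1:5\n7b:a-dman-HEX-1:5\n"
            "LIN\n1:1d(2+1)2n\n2:1o(4+1)3d\n3:3d(2+1)4n\n4:3o(4+1)5d\n"
            "5:5o(3+1)6d\n6:5o(6+1)7d"
        )
        exact = build(n_core, rules, "ncore")
        # the same core carrying one extra Gal is no longer an exact match
        extended_text = n_core.replace("RES\n", "RES\n8b:b-dgal-HEX-1:5\n") + "\n7:6o(2+1)8d"
        extended = build(extended_text, rules, "bigger")
        corpus = [exact, extended, build(DISIALYL_CORE1, rules, "other")]
        assert gt.run_catalog_query("Q1", corpus) == ["ncore"]

    def test_q2_exact_composition(self, rules):
        g1 = build(
            "RES\n1b:b-dglc-HEX-1:5\n2s:n-acetyl\n3s:phosphate\n"
            "LIN\n1:1d(2+1)2n\n2:1o(6+1)3n",
            rules,
            "gp",
        )
        g2 = build("RES\n1b:b-dglc-HEX-1:5\n2s:n-acetyl\nLIN\n1:1d(2+1)2n", rules, "gonly")
        assert gt.run_catalog_query("Q2", [g1, g2]) == ["gp"]

    def test_q3_bag_listing(self, rules):
        g = build(THREE_UND, rules, "671")
        assert gt.run_catalog_query("Q3", [g], structure_id="671") == [1, 2, 3]

    def test_q4_q5(self, rules):
        dis = build(DISIALYL_CORE1, rules, "3456")
        plain = build("RES\n1b:b-dgal-HEX-1:5", rules, "p")
        assert gt.run_catalog_query("Q4", [dis, plain]) == ["3456"]
        assert gt.run_catalog_query("Q5", [dis, plain]) == ["3456"]

    def test_q6_single_residue_cores(self, rules, glcnac_glycan):
        plain = build("RES\n1b:b-dgal-HEX-1:5", rules, "mono")
        assert set(gt.run_catalog_query("Q6", [glcnac_glycan, plain])) == {"glcnac", "mono"}

    def test_unknown_query_id(self, small_corpus):
        with pytest.raises(gt.UnknownQueryId):
            gt.run_catalog_query("Q9", [g for g, _, _ in small_corpus[:2]])
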