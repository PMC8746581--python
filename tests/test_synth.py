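"""Synthetic corpus generator: validity, distributions, planting, labels."""

import numpy as np
import pytest
from scipy import stats

import glycantree as gt
from glycantree.query import library_pattern


class TestRandomGlycan:
    def test_emitted_text_parses_and_rebuilds_isomorphic(self, rules, small_corpus):
        for g, text, _ in small_corpus:
            raw = gt.parse_glycoct(text)
            assert gt.isomorphic(g, gt.build_glycan(raw, rules, g.id))

    def test_seeded_runs_identical(self):
        params = gt.GeneratorParams(seed=9)
        a = gt.random_glycan(params, seed=123)
        b = gt.random_glycan(params, seed=123)
        assert a[1] == b[1]
        c = gt.random_glycan(params, seed=124)
        assert a[1] != c[1]

    def test_fully_defined_when_ambiguity_off(self, rules):
        params = gt.GeneratorParams(
            p_unk=0.0, unknown_anomer_probability=0.0,
            und_distribution={0: 1.0},
        )
        import re

        for seed in range(20):
            g, text, labels = gt.random_glycan(params, seed=seed)
            assert "(-1+" not in text and "+-1)" not in text  # no unknown positions
            assert not re.search(r"\d+b:x-", text)  # no unknown anomers
            assert "UND" not in text
            assert gt.bag_item_count(g) == 0 and labels.planned_bag_size == 0

    def test_planned_bag_size_forced(self, rules):
        params = gt.GeneratorParams(und_distribution={3: 1.0})
        for seed in range(5):
            g, _, labels = gt.random_glycan(params, seed=seed)
            assert gt.bag_item_count(g) == 3 and labels.planned_bag_size == 3

    def test_bag_size_histogram_matches_plan(self):
        params = gt.GeneratorParams()
        n = 600
        seeds = np.random.SeedSequence(515).generate_state(n)
        counts = np.zeros(10, dtype=int)
        for s in seeds:
            _, _, labels = gt.random_glycan(params, seed=int(s) % 2**31)
            counts[labels.planned_bag_size] += 1
        # bin tail so expected counts stay reasonable for the chi-square test
        observed = [counts[0], counts[1], counts[2], counts[3:].sum()]
        probs = params.und_distribution
        expected = np.array([probs[0], probs[1], probs[2], sum(probs[k] for k in range(3, 10))]) * n
        chi = stats.chisquare(observed, expected)
        assert chi.pvalue > 0.01

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            gt.GeneratorParams(p_unk=1.5)
        with pytest.raises(ValueError):
            gt.GeneratorParams(und_distribution={0: 0.5, 1: 0.2})


class TestPlantPattern:
    def test_unblanked_plant_found_by_strict_pattern(self, rules):
        params = gt.GeneratorParams(p_unk=0.0, unknown_anomer_probability=0.0, seed=0)
        g, _, _ = gt.random_glycan(params, seed=11, structure_id="P1")
        planted, labels = gt.plant_pattern(g, "lewis_y", blank_linkages=False, seed=4)
        strict = library_pattern("lewis_y", rules, ambiguity="strict")
        hits = gt.match(strict, planted)
        assert labels.motifs[0][0] == "lewis_y"
        # one of the strict hits is exactly the planted instance
        assert any(
            {rid for _, rid in m.mapping} == set(labels.motifs[0][1]) for m in hits
        )

    def test_blanked_plant_needs_fuzzy(self, rules):
        params = gt.GeneratorParams(p_unk=0.0, unknown_anomer_probability=0.0, seed=0)
        g, _, _ = gt.random_glycan(params, seed=21, structure_id="P2")
        planted, _ = gt.plant_pattern(g, "lewis_b", blank_linkages=True, seed=8)
        fuzzy = library_pattern("lewis_core_fuzzy", rules, ambiguity="fuzzy")
        assert gt.match(fuzzy, planted)

    def test_planted_ids_reference_existing_residues(self, rules):
        params = gt.GeneratorParams(seed=0)
        g, _, _ = gt.random_glycan(params, seed=31, structure_id="P3")
        planted, labels = gt.plant_pattern(g, "lewis_x", seed=2)
        all_ids = {r.id for r in gt.residues(planted, "both")}
        (motif_id, rids) = labels.motifs[0]
        assert set(rids) <= all_ids and len(rids) == 3

    def test_no_attachment_point(self, rules):
        # a lone terminal sialic acid offers no free carbon
        text = (
            "RES\n1b:a-dgro-dgal-NON-2:6|1:a|2:keto|3:d\n2s:n-acetyl\nLIN\n1:1d(5+1)2n"
        )
        g = gt.build_glycan(gt.parse_glycoct(text), rules, id="sia")
        with pytest.raises(gt.NoAttachmentPoint):
            gt.plant_pattern(g, "lewis_y", seed=0)


class TestMakeBenchmark:
    def test_planned_positive_count(self):
        records, glycans, labels = gt.make_benchmark(50, 0.04, seed=1)
        assert len(records) == len(glycans) == len(labels) == 50
        assert sum(lab.is_positive for lab in labels) == 2  # round(50 * 0.04)

    def test_zero_frequency_all_negative(self, rules):
        _, glycans, labels = gt.make_benchmark(30, 0.0, seed=2)
        assert not any(lab.is_positive for lab in labels)
        probe = library_pattern("lewis_core_fuzzy", rules, ambiguity="fuzzy")
        assert not any(gt.match(probe, g) for g in glycans)

    def test_reproducible_and_seed_sensitive(self):
        a = gt.make_benchmark(15, 0.2, seed=7)
        b = gt.make_benchmark(15, 0.2, seed=7)
        c = gt.make_benchmark(15, 0.2, seed=8)
        assert a[0] == b[0]
        assert a[0] != c[0]

    def test_label_soundness(self, rules):
        # every labeled positive is found by the exhaustive oracle with the
        # fuzzy probe; every negative is not
        records, glycans, labels = gt.make_benchmark(60, 0.1, seed=3)
        probe = library_pattern("lewis_core_fuzzy", rules, ambiguity="fuzzy")
        for g, lab in zip(glycans, labels):
            found = bool(gt.brute_force_match(probe, g, guard=40))
            assert found == lab.is_positive, lab.structure_id

    def test_manifest_written(self, tmp_path):
        from glycantree.synth import write_manifest

        _, _, labels = gt.make_benchmark(10, 0.2, seed=4)
        path = tmp_path / "labels.tsv"
        write_manifest(path, labels)
        lines = path.read_text().strip().split("\n")
        assert lines[0].startswith("structure_id")
        assert len(lines) >= 11
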