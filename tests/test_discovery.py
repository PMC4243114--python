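import random

import pytest

from openlbd.cooccurrence import build_all_indices, build_index, candidate_linking_concepts
from openlbd.discovery import (
    DiscoveryConfig,
    discover_targets,
    evaluate_designated,
    percent_useful_ltc,
    rank_targets,
    run_open_discovery,
    useful_linking_set,
)
from openlbd.features import TextEvidence
from openlbd.lexicon import InteractionLexicon, TypeFilterConfig
from openlbd.medline_io import MedlineRecord
from openlbd.synthetic_corpus import (
    CorpusSpec,
    generate_corpus,
    generate_semantic_types,
)


@pytest.fixture(scope="module")
def planted():
    spec = CorpusSpec(
        seed=19,
        n_records=70,
        decoy_b=tuple(f"linkdecoy{i}" for i in range(9)),
        targets=("targetcand0", "targetcand1"),
        interaction_rate=1.0,
    )
    records, truth = generate_corpus(spec)
    return spec, records, truth


class TestDiscoverTargets:
    def test_planted_chain_target_retained_with_linking_set(self, planted):
        spec, records, _ = planted
        mesh = build_index(records, "mesh_field")
        preliminary = candidate_linking_concepts(mesh, spec.start)
        targets = discover_targets(
            set(spec.relevant_b), mesh, preliminary, spec.start,
            type_filter=generate_type_filter(),
            type_map=generate_semantic_types(spec),
        )
        for a in spec.targets:
            assert targets[a] == set(spec.relevant_b)

    def test_target_cooccurring_with_start_excluded(self):
        records = [
            MedlineRecord(pmid="1", title="T.", mesh_terms=("c", "b")),
            MedlineRecord(pmid="2", title="T.", mesh_terms=("b", "a")),
            MedlineRecord(pmid="3", title="T.", mesh_terms=("c", "a")),
        ]
        mesh = build_index(records, "mesh_field")
        targets = discover_targets({"b"}, mesh, {"b"}, "c")
        assert "a" not in targets

    def test_empty_positive_set_warns_empty(self, planted):
        spec, records, _ = planted
        mesh = build_index(records, "mesh_field")
        with pytest.warns(UserWarning, match="empty positive"):
            assert discover_targets(set(), mesh, set(), spec.start) == {}

    def test_matches_three_loop_brute_force(self, planted):
        spec, records, _ = planted
        mesh = build_index(records, "mesh_field")
        preliminary = candidate_linking_concepts(mesh, spec.start)
        positives = set(spec.relevant_b) | set(spec.decoy_b[:3])
        got = discover_targets(positives, mesh, preliminary, spec.start)
        expected = brute_force_targets(records, positives, preliminary, spec.start)
        assert got == expected


def brute_force_targets(records, positives, preliminary, c):
    """Exhaustive reference: scan all record pairs in the MeSH field."""
    result = {}
    all_concepts = {t for r in records for t in r.mesh_terms}
    for a in sorted(all_concepts):
        if a == c or a in preliminary:
            continue
        if any(a in r.mesh_terms and c in r.mesh_terms for r in records):
            continue
        linked = {
            b
            for b in positives
            for r in records
            if a in r.mesh_terms and b in r.mesh_terms and a != b
        }
        if linked:
            result[a] = linked
    return result


def generate_type_filter():
    return TypeFilterConfig(enabled=True)


@pytest.fixture(scope="module")
def evidence_setup():
    # "bone" shares an interaction sentence with the target; "btwo"
    # co-occurs with it in the same abstract only (no interaction word)
    records = [
        MedlineRecord(
            pmid="1", title="Role of atarget.",
            abstract="Bone may increase levels of atarget. Unrelated remark.",
            mesh_terms=("bone", "atarget"),
        ),
        MedlineRecord(
            pmid="2", title="Another report.",
            abstract="Btwo was studied. Later text. Then atarget was found.",
            mesh_terms=("btwo", "atarget"),
        ),
    ]
    lexicon = InteractionLexicon(frozenset({"increase"}))
    evidence = TextEvidence(records, {"bone", "btwo", "atarget"}, lexicon)
    return evidence, lexicon


class TestUsefulLinkingSet:
    def test_rule1_vs_rule2_distinction(self, evidence_setup):
        evidence, lexicon = evidence_setup
        linking = {"bone", "btwo"}
        rule1 = useful_linking_set("atarget", linking, "rule1", evidence, lexicon)
        rule2 = useful_linking_set("atarget", linking, "rule2", evidence, lexicon)
        assert rule1 == {"bone", "btwo"}
        assert rule2 == {"bone"}

    def test_plain_rule_returns_everything(self, evidence_setup):
        evidence, lexicon = evidence_setup
        assert useful_linking_set(
            "atarget", {"bone", "btwo"}, "plain_ltc", evidence, lexicon
        ) == {"bone", "btwo"}

    def test_empty_linking_set(self, evidence_setup):
        evidence, lexicon = evidence_setup
        for rule in ("plain_ltc", "rule1", "rule2"):
            assert useful_linking_set("atarget", set(), rule, evidence, lexicon) == set()

    def test_rule2_requires_lexicon(self, evidence_setup):
        evidence, _ = evidence_setup
        with pytest.raises(ValueError, match="lexicon"):
            useful_linking_set("atarget", {"bone"}, "rule2", evidence, None)

    def test_rule_nesting_on_synthetic_corpus(self, planted, lexicon):
        spec, records, _ = planted
        concepts = {t for r in records for t in r.mesh_terms}
        evidence = TextEvidence(records, concepts, lexicon)
        linking = set(spec.relevant_b) | set(spec.decoy_b)
        for a in spec.targets:
            rule2 = useful_linking_set(a, linking, "rule2", evidence, lexicon)
            rule1 = useful_linking_set(a, linking, "rule1", evidence, lexicon)
            assert rule2 <= rule1 <= linking


class TestRankTargets:
    def test_table_style_dense_ranking(self):
        targets = {
            "alpha": (40, set("abcd"[:4])),
            "beta": (40, {"a", "b", "c", "d"}),
            "gamma": (40, {"a", "b"}),
            "delta": (40, {"a"}),
        }
        ranked = rank_targets(targets)
        assert [t.rank for t in ranked] == [1, 1, 2, 3]

    def test_within_rank_order_alphabetical(self):
        ranked = rank_targets({"zeta": (3, {"x"}), "eta": (3, {"y"})})
        assert [t.concept for t in ranked] == ["eta", "zeta"]

    def test_single_target_rank_one(self):
        assert rank_targets({"only": (2, {"b"})})[0].rank == 1

    def test_matches_counting_oracle_on_random_counts(self):
        rng = random.Random(12)
        for _ in range(50):
            counts = {
                f"t{i}": rng.randint(0, 8) for i in range(rng.randint(1, 15))
            }
            targets = {
                name: (n + 1, {f"b{j}" for j in range(n)})
                for name, n in counts.items()
            }
            ranked = rank_targets(targets)
            for t in ranked:
                distinct_larger = len(
                    {n for n in counts.values() if n > t.useful_ltc}
                )
                assert t.rank == 1 + distinct_larger

    def test_dense_ranks_contiguous(self):
        rng = random.Random(77)
        targets = {
            f"t{i}": (10, {f"b{j}" for j in range(rng.randint(0, 5))})
            for i in range(20)
        }
        ranks = sorted({t.rank for t in rank_targets(targets)})
        assert ranks == list(range(1, len(ranks) + 1))

    def test_type_rank_within_semantic_type(self, planted):
        spec, _, _ = planted
        type_map = generate_semantic_types(spec)
        targets = {
            spec.targets[0]: (5, {"b1", "b2"}),
            spec.targets[1]: (5, {"b1"}),
        }
        ranked = rank_targets(targets, type_map=type_map)
        by_name = {t.concept: t for t in ranked}
        # the two planted targets carry different semantic types, so each
        # is first within its own type
        assert by_name[spec.targets[0]].type_rank == 1
        assert by_name[spec.targets[1]].type_rank == 1
        assert by_name[spec.targets[1]].rank == 2


class TestPercentUsefulLtc:
    def test_zero_and_full(self):
        assert percent_useful_ltc(0, 10) == 0.0
        assert percent_useful_ltc(10, 10) == 100.0

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            percent_useful_ltc(0, 0)

    def test_numerator_bounded(self):
        with pytest.raises(ValueError):
            percent_useful_ltc(5, 3)


class TestRunOpenDiscovery:
    def test_positive_st_linking_subset_of_all(self, planted, lexicon):
        spec, records, _ = planted
        type_map = generate_semantic_types(spec)
        base = DiscoveryConfig(
            start=spec.start, rule="rule1", use_classifier=False,
            type_filter=TypeFilterConfig(enabled=False), seed=1,
        )
        all_report = run_open_discovery(base, records, lexicon, type_map)
        pruned = run_open_discovery(
            DiscoveryConfig(
                start=spec.start, rule="rule1", use_classifier=True,
                type_filter=TypeFilterConfig(enabled=True), seed=1,
            ),
            records, lexicon, type_map,
        )
        assert pruned.active_linking <= all_report.active_linking

    def test_degenerate_configuration_is_plain_cooccurrence(self, planted, lexicon):
        spec, records, _ = planted
        report = run_open_discovery(
            DiscoveryConfig(
                start=spec.start, rule="plain_ltc", use_classifier=False,
                type_filter=TypeFilterConfig(enabled=False), seed=0,
            ),
            records, lexicon, None,
        )
        assert report.active_linking == report.preliminary_linking
        for t in report.targets:
            assert t.useful_ltc == t.ltc

    def test_planted_target_rank_one_under_rule2(self, lexicon):
        spec = CorpusSpec(
            seed=5,
            n_records=110,
            decoy_b=tuple(f"linkdecoy{i}" for i in range(20)),
            targets=("targetcand0",),
            interaction_rate=1.0,
        )
        records, _ = generate_corpus(spec)
        type_map = generate_semantic_types(spec)
        report = run_open_discovery(
            DiscoveryConfig(
                start=spec.start, rule="rule2", use_classifier=True, seed=5,
                designated_target=spec.targets[0],
            ),
            records, lexicon, type_map,
        )
        assert report.evaluation.designated_rank == 1

    def test_no_target_cooccurs_with_start(self, planted, lexicon):
        spec, records, _ = planted
        mesh = build_index(records, "mesh_field")
        report = run_open_discovery(
            DiscoveryConfig(
                start=spec.start, rule="rule1", use_classifier=False,
                type_filter=TypeFilterConfig(enabled=False), seed=0,
            ),
            records, lexicon, None,
        )
        for t in report.targets:
            assert mesh.cooc_of(t.concept, spec.start) == 0


class TestEvaluateDesignated:
    def test_mesh_vs_designated_counts_mesh_cooccurrence(self, planted, lexicon):
        spec, records, _ = planted
        concepts = {t for r in records for t in r.mesh_terms}
        indices = build_all_indices(records, concepts)
        evidence = TextEvidence(records, concepts, lexicon)
        active = set(spec.relevant_b) | set(spec.decoy_b)
        result = evaluate_designated(
            spec.targets[0], active, "mesh_vs_designated",
            indices["mesh_field"], evidence, lexicon,
        )
        assert result.n_useful == len(spec.relevant_b)
        assert result.n_all == len(active)

    def test_bad_mode_errors(self, planted, lexicon):
        spec, records, _ = planted
        concepts = {t for r in records for t in r.mesh_terms}
        indices = build_all_indices(records, concepts)
        evidence = TextEvidence(records, concepts, lexicon)
        with pytest.raises(ValueError, match="mode"):
            evaluate_designated(
                spec.targets[0], {"x"}, "rule9", indices["mesh_field"], evidence
            )
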