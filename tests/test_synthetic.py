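import math

import numpy as np
import pytest

from tcmpattern import (
    GeneratorConfig, demo_thesaurus, generate_cohort, generate_knowledge_base,
    generate_prescriptions, idf_smooth,
)
from tcmpattern.reference import reference_prescriptions
from tcmpattern.synthetic import (
    CLUSTER_SIGNATURES, SHARED_FEATURE_MARGINALS, default_profiles,
    write_cohort_csv, read_cohort_csv, write_prescriptions_csv,
    read_prescriptions_csv,
)
from tcmpattern.vocab import DEFAULT_FEATURE_CATALOG


class TestGeneratorConfig:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            GeneratorConfig(synonym_rate=1.5)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="probability vector"):
            GeneratorConfig(n_clusters=2, cluster_weights=(0.6, 0.6))

    def test_profile_shape_checked(self):
        with pytest.raises(ValueError, match="shape"):
            GeneratorConfig(bernoulli_profiles=np.zeros((2, 3)))

    def test_default_profiles_cover_catalog(self):
        profiles = default_profiles()
        assert profiles.shape == (5, len(DEFAULT_FEATURE_CATALOG))
        assert ((profiles >= 0) & (profiles <= 1)).all()
        # signature features are boosted exactly in their own subgroup
        terms = [t for t, _ in DEFAULT_FEATURE_CATALOG]
        for c, signature in CLUSTER_SIGNATURES.items():
            for t in signature:
                assert profiles[c, terms.index(t)] == 0.80


class TestGenerateCohort:
    def test_deterministic_for_fixed_seed(self, tmp_path):
        cfg = GeneratorConfig(n_cases=150, seed=1)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort_csv(a, pa)
        write_cohort_csv(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_zero_profiles_give_empty_records(self):
        cfg = GeneratorConfig(
            n_cases=30, seed=0,
            bernoulli_profiles=np.zeros((5, len(DEFAULT_FEATURE_CATALOG))),
        )
        assert all(r.raw_terms == [] for r in generate_cohort(cfg))

    def test_case_ids_unique_and_labels_in_range(self):
        cfg = GeneratorConfig(n_cases=100, seed=3)
        records = generate_cohort(cfg)
        assert len({r.case_id for r in records}) == 100
        assert all(0 <= r.true_cluster < 5 for r in records)

    def test_cluster_frequencies_match_profiles(self):
        """Per-subgroup empirical feature frequencies stay within 3
        percentage points of the planted profiles at ~400 cases/subgroup
        (binomial standard error bound)."""
        cfg = GeneratorConfig(n_cases=2000, seed=2, synonym_rate=0.0,
                              missing_rate=0.0,
                              cluster_weights=(0.2,) * 5)
        records = generate_cohort(cfg)
        terms = [t for t, _ in cfg.feature_catalog]
        for c in range(5):
            members = [r for r in records if r.true_cluster == c]
            present = np.zeros((len(members), len(terms)))
            for i, r in enumerate(members):
                for t, _cat in r.raw_terms:
                    present[i, terms.index(t)] = 1
            empirical = present.mean(axis=0)
            assert np.abs(empirical - cfg.bernoulli_profiles[c]).max() < 0.03 + 0.03

    def test_marginals_match_mixture_average(self):
        """Cohort-wide marginals stay within 3 standard errors of the
        weight-averaged profiles for the shared features."""
        cfg = GeneratorConfig(n_cases=2000, seed=9, synonym_rate=0.0,
                              missing_rate=0.0)
        records = generate_cohort(cfg)
        terms = [t for t, _ in cfg.feature_catalog]
        w = np.asarray(cfg.cluster_weights)
        expected = w @ cfg.bernoulli_profiles
        for term, p in SHARED_FEATURE_MARGINALS.items():
            j = terms.index(term)
            count = sum(1 for r in records for t, _ in r.raw_terms if t == term)
            se = math.sqrt(p * (1 - p) / cfg.n_cases)
            assert abs(count / cfg.n_cases - expected[j]) < 3 * se

    def test_synonyms_resolve_through_thesaurus(self):
        cfg = GeneratorConfig(n_cases=300, seed=5, synonym_rate=1.0)
        th = demo_thesaurus()
        raw_terms = [t for r in generate_cohort(cfg) for t, _ in r.raw_terms]
        assert raw_terms, "expected some terms"
        assert all(th.lookup(t) is not None for t in raw_terms)
        # at rate 1.0 nothing is emitted in plain canonical spelling
        assert all(th.lookup(t)[0] != t for t in raw_terms)

    def test_cohort_csv_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_cases=40, seed=6)
        records = generate_cohort(cfg)
        path = tmp_path / "cohort.csv"
        write_cohort_csv(records, path)
        back = read_cohort_csv(path)
        assert [r.case_id for r in back] == [r.case_id for r in records]
        assert [r.gender for r in back] == [r.gender for r in records]
        assert [r.raw_terms for r in back] == [r.raw_terms for r in records]


class TestGenerateKnowledgeBase:
    def test_default_library_has_eight_nonempty_codes(self):
        kb = generate_knowledge_base()
        assert set(kb.codes) == {"LGDH", "DLTF", "RDT", "LKYD",
                                 "LDSD", "SSQD", "RDH", "QDBS"}
        assert all(kb.codes[p] for p in kb.codes)

    def test_every_catalog_term_covered(self):
        kb = generate_knowledge_base()
        covered = {t for doc in kb.codes.values() for t in doc}
        assert {t for t, _ in DEFAULT_FEATURE_CATALOG} <= covered

    def test_random_kb_deterministic_and_covering(self):
        a = generate_knowledge_base(patterns=["p1", "p2", "p3"], seed=4)
        b = generate_knowledge_base(patterns=["p1", "p2", "p3"], seed=4)
        assert a.codes == b.codes
        covered = {t for doc in a.codes.values() for t in doc}
        assert {t for t, _ in DEFAULT_FEATURE_CATALOG} <= covered
        assert all(len(doc) >= 3 for doc in a.codes.values())

    def test_disjoint_documents_have_maximal_idf(self):
        from tcmpattern import KnowledgeBase

        kb = KnowledgeBase({"p1": {"a": 1, "b": 2}, "p2": {"c": 1},
                            "p3": {"d": 3}})
        for t in "abcd":
            assert idf_smooth(t, kb) == pytest.approx(math.log(1 + kb.N))

    def test_too_few_patterns_error(self):
        with pytest.raises(ValueError):
            generate_knowledge_base(patterns=["lonely"])


class TestGeneratePrescriptions:
    def test_schema_contract(self):
        records = generate_prescriptions(seed=0)
        assert len(records) >= 10
        assert {r.kind for r in records} == {"single_herb", "formula"}
        assert len({r.category for r in records}) >= 4
        assert all(r.person_days > 0 and r.avg_daily_dose > 0 for r in records)

    def test_deterministic(self):
        a = generate_prescriptions(seed=2)
        b = generate_prescriptions(seed=2)
        assert [(r.name, r.total_consumption) for r in a] == [
            (r.name, r.total_consumption) for r in b]

    def test_reference_fixture_rows(self):
        records = reference_prescriptions()
        assert len(records) == 20
        by_name = {r.name: r for r in records}
        assert by_name["Hedyotis diffusa Willd."].total_consumption == 553153.5
        ziz = by_name["Zizyphus jujuba Mill var. spinosa"]
        assert ziz.label_as_printed == "Nourish the yin to tranquilize"
        assert ziz.category == "Nourish the heart to tranquilize"

    def test_csv_round_trip(self, tmp_path):
        records = reference_prescriptions()
        path = tmp_path / "rx.csv"
        write_prescriptions_csv(records, path)
        back = read_prescriptions_csv(path)
        assert [(r.name, r.total_consumption, r.category) for r in back] == [
            (r.name, r.total_consumption, r.category) for r in records]
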