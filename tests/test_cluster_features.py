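import numpy as np
import pytest
from scipy.stats import chi2

from tcmpattern import classify_pf, classify_sf, homogeneity_test, summarize_features
from tcmpattern.reference import PRIMARY_FEATURES, SECONDARY_FEATURES

from conftest import make_matrix


class TestHomogeneityTest:
    def test_identical_proportions_give_p_one(self):
        p = homogeneity_test({1: 20, 2: 40}, {1: 100, 2: 200})
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # table [[10,90],[30,70]]: pooled p=0.2, expected [20,80,20,80],
        # sum (O-E)^2/E = 5 + 1.25 + 5 + 1.25 = 12.5 on 1 df
        p = homogeneity_test({1: 10, 2: 30}, {1: 100, 2: 100})
        assert p == pytest.approx(float(chi2.sf(12.5, df=1)))

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            homogeneity_test({1: 0, 2: 0}, {1: 50, 2: 50})
        with pytest.raises(ValueError, match="margin"):
            homogeneity_test({1: 50, 2: 50}, {1: 50, 2: 50})

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            homogeneity_test({1: 5}, {1: 50})

    def test_null_retention_rate(self):
        """A variable with equal 30% prevalence in five clusters of 400 is
        retained (p > 0.05) in at least 90% of simulated cohorts."""
        rng = np.random.default_rng(12)
        n_reps, retained = 200, 0
        for _ in range(n_reps):
            yes = {c: int(rng.binomial(400, 0.30)) for c in range(1, 6)}
            n = {c: 400 for c in range(1, 6)}
            if homogeneity_test(yes, n) > 0.05:
                retained += 1
        assert retained / n_reps >= 0.90


def uniform_cluster_freqs(var_freqs, clusters=(1, 2, 3, 4, 5)):
    return {c: dict(var_freqs) for c in clusters}


class TestClassifyPf:
    def test_homogeneous_common_variable_is_pf(self):
        matrix, model = make_matrix(
            uniform_cluster_freqs({("insomnia", "symptom"): 0.40,
                                   ("rare", "symptom"): 0.02})
        )
        pf = classify_pf(summarize_features(matrix, model))
        assert pf == {"insomnia"}  # the 2% variable fails the frequency floor

    def test_rank_stable_significant_variable_is_pf(self):
        # frequencies differ strongly across clusters (significant), but the
        # variable is rank 1 or 2 everywhere and always above 5%
        freqs = {}
        for c in range(1, 6):
            freqs[c] = {
                ("stable", "symptom"): 0.30 + 0.10 * c,
                ("filler1", "symptom"): 0.20,
                ("filler2", "symptom"): 0.10,
            }
        matrix, model = make_matrix(freqs)
        summaries = summarize_features(matrix, model)
        stable = next(s for s in summaries if s.variable == "stable")
        assert stable.chi2_p < 0.05
        assert "stable" in classify_pf(summaries)

    def test_rank_unstable_significant_variable_is_not_pf(self):
        # tongue-appearance gap limit is 3: ranks swing 1..5 -> excluded
        freqs = {}
        base = ["ta1", "ta2", "ta3", "ta4", "ta5"]
        for c in range(1, 6):
            order = base[c - 1:] + base[: c - 1]  # rotate leaders
            freqs[c] = {(v, "tongue_appearance"): 0.50 - 0.08 * i
                        for i, v in enumerate(order)}
        matrix, model = make_matrix(freqs)
        summaries = summarize_features(matrix, model)
        assert classify_pf(summaries) == set()

    def test_absent_variable_fails_rank_gap(self):
        freqs = uniform_cluster_freqs({("present", "pulse"): 0.30,
                                       ("patchy", "pulse"): 0.30})
        freqs[5][("patchy", "pulse")] = 0.0  # missing from one cluster
        matrix, model = make_matrix(freqs)
        summaries = summarize_features(matrix, model)
        patchy = next(s for s in summaries if s.variable == "patchy")
        assert patchy.per_cluster_rank[5] == 2  # one past the present count
        assert "patchy" not in classify_pf(summaries)

    def test_pf_invariant_under_cluster_relabeling(self):
        freqs = {
            c: {("a", "symptom"): 0.40, ("b", "symptom"): 0.05 + 0.1 * c}
            for c in range(1, 6)
        }
        matrix, model = make_matrix(freqs)
        pf1 = classify_pf(summarize_features(matrix, model))
        relabel = {1: 5, 2: 4, 3: 3, 4: 2, 5: 1}
        model.assignments = {cid: relabel[c] for cid, c in model.assignments.items()}
        pf2 = classify_pf(summarize_features(matrix, model))
        assert pf1 == pf2


class TestClassifySf:
    def test_floor_excludes_low_frequency(self):
        freqs = uniform_cluster_freqs({("common", "symptom"): 0.30},
                                      clusters=(1, 2))
        freqs[1][("marginal", "symptom")] = 0.049
        freqs[2][("marginal", "symptom")] = 0.20
        matrix, model = make_matrix(freqs, n_per_cluster=1000)
        summaries = summarize_features(matrix, model)
        sf = classify_sf(summaries, pf={"common"})
        assert ("marginal", 0.049) not in sf[1]["symptom"]
        assert [t for t, _ in sf[2]["symptom"]] == ["marginal"]

    def test_pf_never_in_sf(self):
        matrix, model = make_matrix(
            uniform_cluster_freqs({("a", "symptom"): 0.40,
                                   ("b", "symptom"): 0.30})
        )
        summaries = summarize_features(matrix, model)
        pf = classify_pf(summaries)
        sf = classify_sf(summaries, pf)
        sf_terms = {t for by_cat in sf.values() for lst in by_cat.values()
                    for t, _ in lst}
        assert pf & sf_terms == set()

    def test_descending_frequency_with_lexicographic_ties(self):
        freqs = {1: {("zz", "symptom"): 0.30, ("aa", "symptom"): 0.30,
                     ("mid", "symptom"): 0.50},
                 2: {("zz", "symptom"): 0.30, ("aa", "symptom"): 0.30,
                     ("mid", "symptom"): 0.50}}
        matrix, model = make_matrix(freqs)
        sf = classify_sf(summarize_features(matrix, model), pf=set())
        assert [t for t, _ in sf[1]["symptom"]] == ["mid", "aa", "zz"]

    def test_reproduces_published_cluster1_symptom_list(self):
        """Engineered cluster-1 frequencies reproduce the published S1
        symptom list: eight entries led by profuse dreaming."""
        published = SECONDARY_FEATURES[1]["symptom"]
        freqs = {
            1: {(t, "symptom"): 0.40 - 0.03 * i
                for i, t in enumerate(published)},
            2: {(t, "symptom"): 0.02 for t in published},
        }
        matrix, model = make_matrix(freqs)
        sf = classify_sf(summarize_features(matrix, model), pf=set())
        assert [t for t, _ in sf[1]["symptom"]] == list(published)
        assert sf[1]["symptom"][0][0] == "profuse dreaming"

    def test_raising_floor_never_adds_entries(self):
        rng = np.random.default_rng(4)
        freqs = {
            c: {(f"v{j}", "symptom"): float(rng.uniform(0, 0.3))
                for j in range(8)}
            for c in (1, 2, 3)
        }
        matrix, model = make_matrix(freqs, n_per_cluster=500)
        summaries = summarize_features(matrix, model)
        previous = None
        for floor in (0.02, 0.05, 0.10, 0.20):
            entries = {
                (c, cat, t)
                for c, by_cat in classify_sf(summaries, set(), floor).items()
                for cat, lst in by_cat.items() for t, _ in lst
            }
            if previous is not None:
                assert entries <= previous
            previous = entries


class TestEngineeredPfFixture:
    def test_reproduces_published_pf_set(self):
        """A cohort engineered so the twelve published primary features are
        homogeneous and common while everything else swings across clusters
        yields exactly the published PF set."""
        pf_freq = {
            "insomnia": 0.387, "dry mouth": 0.315, "lack of strength": 0.171,
            "dizziness": 0.144, "loss of appetite": 0.138,
            "bitter taste of mouth": 0.085, "abdominal distention": 0.10,
            "headache": 0.069, "loose stool": 0.07, "nausea": 0.066,
            "slippery pulse": 0.19, "rapid pulse": 0.12,
        }
        categories = {"slippery pulse": "pulse", "rapid pulse": "pulse"}
        others = ["profuse dreaming", "lumbago", "afraid of cold",
                  "nocturia", "cough", "soreness", "dry eyes",
                  "acid regurgitation", "absence of thirst", "back pain"]
        freqs = {}
        for c in range(1, 6):
            f = {(t, categories.get(t, "symptom")): v
                 for t, v in pf_freq.items()}
            # non-PF variables: one dominant per cluster, rare elsewhere
            for i, t in enumerate(others):
                f[(t, "symptom")] = 0.60 if i % 5 == c - 1 else 0.03
            freqs[c] = f
        matrix, model = make_matrix(freqs, n_per_cluster=400)
        pf = classify_pf(summarize_features(matrix, model))
        assert pf == set(PRIMARY_FEATURES)
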