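import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from phenominer import pipeline
from phenominer.corpus import (
    AbstractRecord,
    DiseaseCorpus,
    generate_synthetic,
    synthetic_ontology,
)
from phenominer.filtering import (
    DiseaseModel,
    EvaluationResult,
    FilterParams,
    compute_stats,
    density,
    evaluate,
    extend_candidates,
    learn_parameters,
    min_density_subset,
    run_filter,
    select_seeds,
)
from phenominer.ontology import ICTable, Ontology, OntologyTerm, term_frequencies


def make_corpus(spec: dict[str, list[set[str]]]) -> DiseaseCorpus:
    """Build a corpus directly from disease -> list of per-abstract term sets."""
    corpus = DiseaseCorpus()
    for disease, abstract_terms in spec.items():
        for k, terms in enumerate(abstract_terms):
            aid = f"{disease}-a{k}"
            corpus.abstracts[aid] = AbstractRecord(aid, "t", "b", frozenset({disease}))
            corpus.disease_abstracts.setdefault(disease, set()).add(aid)
            corpus.raw_mentions[aid] = set(terms)
    return corpus


def flat_ic(terms, value=1.0) -> ICTable:
    return ICTable(
        frequency={t: math.exp(-value) for t in terms},
        ic={t: value for t in terms},
        n_items=1,
    )


class TestComputeStats:
    def test_idf_and_tfidf_arithmetic(self):
        # T_D = 4; term X mentioned by 2 diseases; tf = 3 for D1
        corpus = make_corpus(
            {
                "D1": [{"X"}, {"X"}, {"X"}],
                "D2": [{"X", "Y"}],
                "D3": [{"Y"}],
                "D4": [{"Y"}],
            }
        )
        stats = {
            (s.disease, s.term): s
            for s in compute_stats(corpus, flat_ic({"X", "Y"}, 2.0))
        }
        s = stats[("D1", "X")]
        assert s.tf == 3
        assert s.idf == pytest.approx(math.log(2), abs=1e-4)
        assert s.tfidf == pytest.approx(3 * math.log(2), abs=1e-3)
        assert s.tfidf == pytest.approx(2.079, abs=1e-3)
        assert s.tfidfic == pytest.approx(s.tfidf * 2.0)

    def test_ubiquitous_term_has_zero_weight(self):
        corpus = make_corpus({"D1": [{"X"}], "D2": [{"X"}]})
        stats = compute_stats(corpus, flat_ic({"X"}))
        assert all(s.idf == 0.0 and s.tfidf == 0.0 for s in stats)

    def test_tf_bounded_by_abstract_count(self):
        corpus = make_corpus({"D1": [{"X"}, {"X"}, set()]})
        (s,) = [s for s in compute_stats(corpus, flat_ic({"X"})) if s.term == "X"]
        assert s.tf == 2 <= 3

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            compute_stats(DiseaseCorpus(), flat_ic(set()))


class TestSelectSeeds:
    def _stats(self, tfidfs: dict[str, float]):
        return [
            type("S", (), {"term": t, "tfidf": v})() for t, v in tfidfs.items()
        ]

    def test_zero_threshold_keeps_all(self):
        seeds, leftovers = select_seeds(self._stats({"a": 5, "b": 0}), 0)
        assert seeds == {"a", "b"} and leftovers == set()

    def test_unreachable_threshold_leaves_no_seed(self):
        seeds, leftovers = select_seeds(self._stats({"a": 5, "b": 3}), 99)
        assert seeds == set() and leftovers == {"a", "b"}

    def test_threshold_tie_included(self):
        seeds, _ = select_seeds(self._stats({"a": 5, "b": 3, "c": 1}), 3)
        assert seeds == {"a", "b"}


@pytest.fixture(scope="module")
def path_ontology():
    """a, b siblings under P; c six edges from both (chain below P)."""
    chain = [OntologyTerm("T:R", "root"), OntologyTerm("T:P", "p", parents=("T:R",))]
    chain += [
        OntologyTerm("T:A", "a", parents=("T:P",)),
        OntologyTerm("T:B", "b", parents=("T:P",)),
    ]
    prev = "T:P"
    for k in range(1, 5):
        chain.append(OntologyTerm(f"T:Q{k}", f"q{k}", parents=(prev,)))
        prev = f"T:Q{k}"
    chain.append(OntologyTerm("T:C", "c", parents=(prev,)))
    return Ontology(chain)


class TestDensity:
    def test_pair_has_zero_density(self, path_ontology):
        assert density(path_ontology, {"T:A", "T:B"}) == 0.0

    def test_constant_distances_zero(self):
        onto = Ontology(
            [OntologyTerm("T:R", "root")]
            + [OntologyTerm(f"T:{i}", f"s{i}", parents=("T:R",)) for i in range(3)]
        )
        assert density(onto, {"T:0", "T:1", "T:2"}) == 0.0

    def test_mixed_distances(self, path_ontology):
        # pairwise distances {2, 6, 6} -> population SD
        d = density(path_ontology, {"T:A", "T:B", "T:C"})
        assert d == pytest.approx(np.std([2, 6, 6]), abs=1e-12)
        assert d == pytest.approx(1.8856, abs=1e-4)

    def test_singleton_rejected(self, path_ontology):
        with pytest.raises(ValueError):
            density(path_ontology, {"T:A"})


def brute_force_min_density(onto, group):
    """Independent oracle: enumerate all subsets with exact rational keys."""
    terms = sorted(group)
    best_key, best = None, None
    for size in range(2, len(terms) + 1):
        for combo in itertools.combinations(terms, size):
            dists = [
                onto.shortest_path_length(a, b)
                for a, b in itertools.combinations(combo, 2)
            ]
            n = len(dists)
            mean = Fraction(sum(dists), n)
            var = sum((Fraction(d) - mean) ** 2 for d in dists) / n
            key = (var, -size, mean, combo)
            if best_key is None or key < best_key:
                best_key, best = key, set(combo)
    return best


class TestMinDensitySubset:
    def test_pair_returned_as_is(self, path_ontology):
        assert min_density_subset(path_ontology, {"T:A", "T:C"}) == {"T:A", "T:C"}

    def test_singleton_returned_as_is(self, path_ontology):
        assert min_density_subset(path_ontology, {"T:A"}) == {"T:A"}

    def test_tie_break_prefers_smaller_mean_distance(self, path_ontology):
        # all pairs have SD 0; {a,b} (distance 2) beats {a,c}/{b,c} (distance 6)
        assert min_density_subset(path_ontology, {"T:A", "T:B", "T:C"}) == {
            "T:A",
            "T:B",
        }

    def test_constant_distance_group_kept_whole(self):
        onto = Ontology(
            [OntologyTerm("T:R", "root")]
            + [OntologyTerm(f"T:{i}", f"s{i}", parents=("T:R",)) for i in range(4)]
        )
        group = {f"T:{i}" for i in range(4)}
        assert min_density_subset(onto, group) == group

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            onto = synthetic_ontology(
                n_top_level=2, terms_per_group=12, seed=100 + trial
            )
            terms = sorted(onto)
            size = int(rng.integers(3, 11))
            group = set(rng.choice(terms, size=size, replace=False))
            assert min_density_subset(onto, group) == brute_force_min_density(
                onto, group
            )

    def test_heuristic_never_worse_than_whole_group(self):
        onto = synthetic_ontology(n_top_level=3, terms_per_group=20, seed=9)
        rng = np.random.default_rng(5)
        terms = sorted(onto)
        group = set(rng.choice(terms, size=16, replace=False))  # above exact cap
        subset = min_density_subset(onto, group)
        assert len(subset) >= 2
        assert density(onto, subset) <= density(onto, group)
        # deterministic
        assert min_density_subset(onto, group) == subset


def _ts(term, tfidfic):
    return type("S", (), {"term": term, "tfidfic": tfidfic})()


class TestExtendCandidates:
    def test_huge_margin_accepts_all_survivors(self, path_ontology):
        seed = {"T:A", "T:B"}
        accepted = extend_candidates(
            path_ontology, seed, 0.0, [_ts("T:C", 9.0), _ts("T:Q1", 1.0)], m=0.5, e=1e9
        )
        assert accepted == {"T:C", "T:Q1"}

    def test_tfidfic_prune_applies_first(self, path_ontology):
        accepted = extend_candidates(
            path_ontology, {"T:A", "T:B"}, 0.0, [_ts("T:C", 0.4)], m=0.5, e=1e9
        )
        assert accepted == set()

    def test_zero_margin_rejects_density_changers(self, path_ontology):
        # adding C to {A, B} moves SD from 0 to ~1.886
        accepted = extend_candidates(
            path_ontology, {"T:A", "T:B"}, 0.0, [_ts("T:C", 9.0)], m=0.0, e=0.0
        )
        assert accepted == set()

    def test_equidistant_term_keeps_zero_density(self, path_ontology):
        # Q1 is 2 edges from both A and B: distances {2,2,2}, SD stays 0
        accepted = extend_candidates(
            path_ontology, {"T:A", "T:B"}, 0.0, [_ts("T:Q1", 9.0)], m=0.0, e=0.0
        )
        assert accepted == {"T:Q1"}

    def test_margin_monotonicity(self, path_ontology):
        leftovers = [_ts("T:C", 9.0), _ts("T:Q1", 5.0), _ts("T:Q4", 2.0)]
        prev: set[str] = set()
        for e in (0.0, 0.5, 1.0, 2.0, 5.0):
            acc = extend_candidates(
                path_ontology, {"T:A", "T:B"}, 0.0, leftovers, m=0.0, e=e
            )
            assert prev <= acc
            prev = acc


@pytest.fixture(scope="module")
def noisy_setup():
    onto = synthetic_ontology(seed=21)
    records, truth, cats = generate_synthetic(onto, noise_rate=2.0, seed=21)
    corpus = pipeline.annotate_corpus(onto, records, sorted(truth.planted))
    return onto, corpus, truth, cats


class TestRunFilter:
    def test_noiseless_zero_threshold_is_subset_with_perfect_precision(self):
        onto = synthetic_ontology(seed=6)
        records, truth, _ = generate_synthetic(
            onto, n_diseases=8, mention_prob=1.0, noise_rate=0.0, seed=6
        )
        corpus = pipeline.annotate_corpus(onto, records, sorted(truth.planted))
        models, _ = pipeline.derive_models(onto, corpus, FilterParams(n=0, m=0, e=5.0))
        res = evaluate(models, truth.planted)
        assert res.precision == 1.0
        for d, m in models.items():
            assert m.candidates <= truth.planted[d]
            assert m.candidates

    def test_disease_without_terms_yields_empty_model(self):
        onto = synthetic_ontology(seed=1)
        term = sorted(onto.descendants(onto.abnormality_root))[5]
        corpus = make_corpus({"D1": [{term}], "D2": [set()]})
        models = run_filter(onto, corpus, flat_ic({term}), FilterParams())
        assert models["D2"].is_empty
        assert not models["D1"].is_empty

    def test_output_subset_of_raw_terms(self, noisy_setup):
        onto, corpus, truth, _ = noisy_setup
        models, _ = pipeline.derive_models(onto, corpus, FilterParams(n=2, m=2, e=1.0))
        for d, m in models.items():
            assert m.candidates <= corpus.disease_terms(d)

    def test_filter_improves_f_score_over_raw(self, noisy_setup):
        onto, corpus, truth, _ = noisy_setup
        models, _ = pipeline.derive_models(onto, corpus, FilterParams(n=5, m=5, e=1.0))
        raw = {
            d: DiseaseModel(disease=d, candidates=corpus.disease_terms(d))
            for d in truth.planted
        }
        assert (
            evaluate(models, truth.planted).f_score
            > evaluate(raw, truth.planted).f_score
        )

    def test_seed_threshold_monotonicity(self, noisy_setup):
        onto, corpus, _, _ = noisy_setup
        ic = pipeline.abstract_level_ic(onto, corpus)
        stats = compute_stats(corpus, ic)
        disease = sorted(corpus.disease_abstracts)[0]
        d_stats = [s for s in stats if s.disease == disease]
        prev_seeds = None
        for n in (0.0, 2.0, 5.0, 10.0, 50.0):
            seeds, _ = select_seeds(d_stats, n)
            if prev_seeds is not None:
                assert seeds <= prev_seeds
            prev_seeds = seeds

    def test_per_category_override_changes_result(self, noisy_setup):
        onto, corpus, truth, cats = noisy_setup
        category_map = {d: sorted(cs)[0] for d, cs in cats.items()}
        strict = FilterParams(n=1e6, m=1e6, e=0.0)
        models = run_filter(
            onto,
            corpus,
            pipeline.abstract_level_ic(onto, corpus),
            FilterParams(n=0, m=0, e=10.0),
            per_category_params={"CAT00": strict},
            category_map=category_map,
        )
        overridden = [d for d, c in category_map.items() if c == "CAT00"]
        # strict params force the one-term fallback for overridden diseases
        assert all(len(models[d].candidates) == 1 for d in overridden)
        others = [d for d in category_map if category_map[d] != "CAT00"]
        assert any(len(models[d].candidates) > 1 for d in others)


class TestEvaluate:
    def test_identity_is_perfect(self):
        models = {"D1": DiseaseModel("D1", candidates={"a", "b"})}
        res = evaluate(models, {"D1": {"a", "b"}})
        assert (res.precision, res.recall, res.f_score) == (1.0, 1.0, 1.0)

    def test_harmonic_mean_arithmetic(self):
        models = {"D1": DiseaseModel("D1", candidates=set("abcdefghij"))}
        gold = {"D1": set("abcdef") | set("klmnopqrs")}
        res = evaluate(models, gold)
        assert (res.tp, res.fp, res.fn) == (6, 4, 9)
        assert res.precision == pytest.approx(0.6)
        assert res.recall == pytest.approx(0.4)
        assert res.f_score == pytest.approx(0.48)

    def test_empty_model_flags_undefined_precision(self):
        models = {"D1": DiseaseModel("D1")}
        res = evaluate(models, {"D1": {"a"}})
        assert res.recall == 0.0 and res.precision == 0.0
        assert not res.precision_defined

    def test_subsumption_mode_credits_ancestor(self, head_skeleton_ontology):
        models = {"D1": DiseaseModel("D1", candidates={"HS:CRH"})}
        gold = {"D1": {"HS:CAH"}}
        exact = evaluate(models, gold)
        subs = evaluate(
            models, gold, match_mode="subsumption", ontology=head_skeleton_ontology
        )
        assert exact.tp == 0
        assert (subs.tp, subs.fp, subs.fn) == (1, 0, 0)

    def test_unknown_gold_disease_rejected(self):
        with pytest.raises(KeyError):
            evaluate({}, {"D9": {"a"}})


class TestLearnParameters:
    def test_single_grid_point_returned(self, noisy_setup):
        onto, corpus, truth, cats = noisy_setup
        category_map = {d: sorted(cs)[0] for d, cs in cats.items()}
        ic = pipeline.abstract_level_ic(onto, corpus)
        grid = {"n": [3.0], "m": [4.0], "e": [1.5]}
        learned = learn_parameters(
            onto, corpus, ic, truth.planted, category_map, grid
        )
        for lp in learned.values():
            assert lp.params == FilterParams(n=3.0, m=4.0, e=1.5)

    def test_learner_dominates_every_grid_point(self, noisy_setup):
        onto, corpus, truth, cats = noisy_setup
        category_map = {d: sorted(cs)[0] for d, cs in cats.items()}
        ic = pipeline.abstract_level_ic(onto, corpus)
        grid = {"n": [0.0, 5.0, 20.0], "m": [0.0, 5.0], "e": [0.5, 2.0]}
        learned = learn_parameters(
            onto, corpus, ic, truth.planted, category_map, grid
        )
        category = sorted(learned)[0]
        cat_diseases = [d for d, c in category_map.items() if c == category]
        cat_gold = {d: truth.planted[d] for d in cat_diseases}
        for n in grid["n"]:
            for m in grid["m"]:
                for e in grid["e"]:
                    models = run_filter(
                        onto, corpus, ic, FilterParams(n=n, m=m, e=e)
                    )
                    score = evaluate(
                        {d: models[d] for d in cat_diseases}, cat_gold
                    ).f_score
                    assert learned[category].objective >= score - 1e-12

    def test_precision_objective_reaches_one_on_noiseless_corpus(self):
        onto = synthetic_ontology(seed=13)
        records, truth, cats = generate_synthetic(
            onto, n_diseases=6, mention_prob=1.0, noise_rate=0.0, seed=13
        )
        corpus = pipeline.annotate_corpus(onto, records, sorted(truth.planted))
        category_map = {d: sorted(cs)[0] for d, cs in cats.items()}
        learned = learn_parameters(
            onto,
            corpus,
            pipeline.abstract_level_ic(onto, corpus),
            truth.planted,
            category_map,
            {"n": [0.0, 1e6], "m": [0.0], "e": [1.0]},
            objective="precision",
        )
        assert all(lp.objective == 1.0 for lp in learned.values())

    def test_category_without_gold_skipped(self, noisy_setup):
        onto, corpus, truth, cats = noisy_setup
        category_map = {d: sorted(cs)[0] for d, cs in cats.items()}
        some_disease = sorted(truth.planted)[0]
        gold = {some_disease: truth.planted[some_disease]}
        learned = learn_parameters(
            onto,
            corpus,
            pipeline.abstract_level_ic(onto, corpus),
            gold,
            category_map,
            {"n": [1.0], "m": [1.0], "e": [1.0]},
        )
        assert set(learned) == {category_map[some_disease]}
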