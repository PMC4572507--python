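"""Disease-model filtering: TFIDF/TFIDFIC weighting and density clustering.

Diseases play the role of documents.  For a disease D and ontology term t:

* TF(t, D)     — number of D-associated abstracts mentioning t at least once
  (multiple mentions within one abstract count once);
* IDF(t, D)    — log(T_D / number of diseases mentioning t), T_D the total
  number of diseases in the corpus;
* TFIDF(t, D)  — TF x IDF;
* TFIDFIC(t,D) — TFIDF x IC(t), with IC from abstract-level annotation
  frequencies, rewarding specific terms.

The filter itself has three tunable thresholds (n, m, e).  Terms with
TFIDF >= n become clustering seeds; the seeds are grouped by top-level
organ-system category and each group is reduced to its minimum-density
subset, where the density of a term set is the population standard
deviation of all pairwise shortest-path lengths in the ontology (a tight
cluster of terms has low density).  Leftover terms surviving a TFIDFIC >= m
prune may then rejoin a group's subset if adding them keeps the density
within a margin e of the seed density.  Parameters can be learned per
disease category by exhaustive grid search against a gold standard.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .corpus import DiseaseCorpus
from .ontology import ICTable, Ontology, TermId

__all__ = [
    "TermStats",
    "FilterParams",
    "DiseaseModel",
    "EvaluationResult",
    "compute_stats",
    "select_seeds",
    "density",
    "min_density_subset",
    "extend_candidates",
    "run_filter",
    "evaluate",
    "learn_parameters",
]

logger = logging.getLogger(__name__)

EXACT_SEARCH_MAX = 12  # exhaustive subset search up to this group size


@dataclass(frozen=True)
class TermStats:
    """Weights of one (disease, term) pair."""

    disease: str
    term: TermId
    tf: int
    idf: float
    tfidf: float
    ic: float
    tfidfic: float


@dataclass(frozen=True)
class FilterParams:
    """The filter's three thresholds.

    n : TFIDF seed threshold (terms at or above become clustering seeds)
    m : TFIDFIC pruning threshold for leftover terms
    e : density margin for accepting a leftover into a cluster
    """

    n: float = 5.0
    m: float = 5.0
    e: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 0 or self.m < 0 or self.e < 0:
            raise ValueError("filter parameters must be non-negative")


@dataclass
class DiseaseModel:
    """Final filtered term set for one disease.

    ``provenance`` records how each candidate entered the model:
    "seed-subset" (member of a minimum-density seed cluster),
    "density-extended" (leftover accepted within the density margin), or
    "fallback" (seedless disease, single best-TFIDF term).
    """

    disease: str
    candidates: set[TermId] = field(default_factory=set)
    provenance: dict[TermId, str] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.candidates


@dataclass
class EvaluationResult:
    """Precision/recall/F of model term sets against a gold standard.

    Undefined ratios (zero denominators) are reported as 0.0 with the
    corresponding flag set.
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    precision_defined: bool = True
    recall_defined: bool = True
    per_disease: dict[str, "EvaluationResult"] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvaluationResult":
        p_def = (tp + fp) > 0
        r_def = (tp + fn) > 0
        precision = tp / (tp + fp) if p_def else 0.0
        recall = tp / (tp + fn) if r_def else 0.0
        f = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        return cls(tp, fp, fn, precision, recall, f, p_def, r_def)


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------


def compute_stats(
    corpus: DiseaseCorpus, ic_table: ICTable, log_base: float | None = None
) -> list[TermStats]:
    """TF, IDF, TFIDF, IC and TFIDFIC for every (disease, term) with TF >= 1.

    ``ic_table`` should be the abstract-level IC computed on the same
    corpus.  Terms whose IC is undefined (never annotated) contribute
    TFIDFIC = 0 so they can never survive the specificity prune.
    """
    t_d = corpus.n_diseases
    if t_d == 0:
        raise ValueError("corpus contains no diseases")
    doc_freq: dict[TermId, int] = {}
    disease_term_sets = {
        d: corpus.disease_terms(d) for d in corpus.disease_abstracts
    }
    for terms in disease_term_sets.values():
        for t in terms:
            doc_freq[t] = doc_freq.get(t, 0) + 1

    def _log(x: float) -> float:
        return math.log(x) if log_base is None else math.log(x, log_base)

    stats: list[TermStats] = []
    for disease in sorted(corpus.disease_abstracts):
        abstract_ids = corpus.disease_abstracts[disease]
        tf_counts: dict[TermId, int] = {}
        for aid in abstract_ids:
            for t in corpus.raw_mentions.get(aid, ()):
                tf_counts[t] = tf_counts.get(t, 0) + 1
        for term in sorted(tf_counts):
            tf = tf_counts[term]
            idf = max(0.0, _log(t_d / doc_freq[term]))
            tfidf = tf * idf
            ic = ic_table.ic.get(term, math.inf)
            tfidfic = tfidf * ic if math.isfinite(ic) else 0.0
            stats.append(
                TermStats(
                    disease=disease,
                    term=term,
                    tf=tf,
                    idf=idf,
                    tfidf=tfidf,
                    ic=ic if math.isfinite(ic) else float("inf"),
                    tfidfic=tfidfic,
                )
            )
    return stats


def stats_to_frame(stats: Iterable[TermStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.disease, s.term, s.tf, s.idf, s.tfidf, s.ic, s.tfidfic)
            for s in stats
        ],
        columns=["disease_id", "term_id", "tf", "idf", "tfidf", "ic", "tfidfic"],
    )


def select_seeds(
    stats: Sequence[TermStats], n: float
) -> tuple[set[TermId], set[TermId]]:
    """Split one disease's terms into seeds (TFIDF >= n) and leftovers."""
    if not stats:
        raise ValueError("stats must be non-empty")
    seeds = {s.term for s in stats if s.tfidf >= n}
    leftovers = {s.term for s in stats} - seeds
    return seeds, leftovers


# ---------------------------------------------------------------------------
# Density clustering
# ---------------------------------------------------------------------------


def _distance_matrix(ontology: Ontology, terms: Sequence[TermId]) -> np.ndarray:
    k = len(terms)
    dist = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            d = ontology.shortest_path_length(terms[i], terms[j])
            dist[i, j] = dist[j, i] = d
    return dist


def density(ontology: Ontology, terms: Iterable[TermId]) -> float:
    """Population SD of all pairwise shortest-path lengths in *terms*."""
    ts = sorted(set(terms))
    if len(ts) < 2:
        raise ValueError("density requires at least two terms")
    dist = _distance_matrix(ontology, ts)
    iu = np.triu_indices(len(ts), k=1)
    return float(np.std(dist[iu]))


def _subset_key(
    dist: np.ndarray, idx: tuple[int, ...], terms: Sequence[TermId]
) -> tuple:
    """Exact comparison key: (variance, -size, mean distance, ids).

    Distances are integers, so variance and mean are exact rationals;
    comparing Fractions avoids float ties resolving differently across
    platforms.
    """
    k = len(idx)
    s = 0
    ssq = 0
    for a in range(k):
        for b in range(a + 1, k):
            d = int(dist[idx[a], idx[b]])
            s += d
            ssq += d * d
    npairs = k * (k - 1) // 2
    var = Fraction(npairs * ssq - s * s, npairs * npairs)
    mean = Fraction(s, npairs)
    return (var, -k, mean, tuple(terms[i] for i in idx))


def min_density_subset(
    ontology: Ontology,
    group: Iterable[TermId],
    exact_max: int = EXACT_SEARCH_MAX,
) -> set[TermId]:
    """The subset of *group* (size >= 2) minimizing density.

    Groups up to ``exact_max`` terms are searched exhaustively.  Larger
    groups use an assignment-based heuristic: terms are ordered by mutual
    proximity (seeded from a minimum-cost assignment over the pairwise
    distance matrix, then grown greedily by mean distance to the selected
    set) and all prefixes of the ordering are scored.  Ties are broken by
    larger subset, then smaller mean pairwise distance, then
    lexicographically smallest id tuple.  Singleton groups return
    themselves.
    """
    terms = sorted(set(group))
    if not terms:
        raise ValueError("group must be non-empty")
    if len(terms) <= 2:
        return set(terms)
    dist = _distance_matrix(ontology, terms)
    k = len(terms)
    if k <= exact_max:
        candidate_idx = (
            idx
            for size in range(2, k + 1)
            for idx in itertools.combinations(range(k), size)
        )
    else:
        order = _proximity_order(dist)
        candidate_idx = (tuple(sorted(order[:size])) for size in range(2, k + 1))
    best_idx = min(candidate_idx, key=lambda idx: _subset_key(dist, idx, terms))
    return {terms[i] for i in best_idx}


def _proximity_order(dist: np.ndarray) -> list[int]:
    """Order terms by mutual proximity for the heuristic prefix scan.

    A minimum-cost assignment (each term paired with a distinct partner)
    identifies the tightest pair as the starting core; remaining terms are
    appended greedily by smallest mean distance to the selected set.
    """
    k = dist.shape[0]
    cost = dist.astype(float).copy()
    np.fill_diagonal(cost, np.inf)
    rows, cols = linear_sum_assignment(cost)
    pair_costs = [(cost[r, c], r, c) for r, c in zip(rows, cols)]
    _, r0, c0 = min(pair_costs)
    selected = [min(r0, c0), max(r0, c0)]
    remaining = [i for i in range(k) if i not in selected]
    while remaining:
        nxt = min(remaining, key=lambda i: (dist[i, selected].mean(), i))
        selected.append(nxt)
        remaining.remove(nxt)
    return selected


def extend_candidates(
    ontology: Ontology,
    seed_subset: Iterable[TermId],
    seed_density: float,
    leftovers: Sequence[TermStats],
    m: float,
    e: float,
) -> set[TermId]:
    """Leftover terms accepted into a cluster within the density margin.

    Leftovers below the TFIDFIC threshold ``m`` are pruned.  Each survivor
    is appended provisionally to the seed subset and kept iff the density
    of the augmented set stays within ``e`` of the seed density.  Each
    term is judged against the seed subset independently, which makes the
    outcome order-independent and monotone in ``e``; survivors are still
    processed in descending-TFIDFIC order (term-id tie-break) for
    deterministic reporting.
    """
    seed = sorted(set(seed_subset))
    if not seed:
        raise ValueError("seed_subset must be non-empty")
    survivors = sorted(
        (ts for ts in leftovers if ts.tfidfic >= m),
        key=lambda ts: (-ts.tfidfic, ts.term),
    )
    accepted: set[TermId] = set()
    for ts in survivors:
        if ts.term in seed:
            continue
        trial = set(seed) | {ts.term}
        if len(trial) < 2:
            continue
        if abs(density(ontology, trial) - seed_density) <= e:
            accepted.add(ts.term)
    return accepted


# ---------------------------------------------------------------------------
# The full per-disease filter
# ---------------------------------------------------------------------------


def _filter_disease(
    ontology: Ontology, stats: Sequence[TermStats], params: FilterParams
) -> DiseaseModel:
    disease = stats[0].disease
    model = DiseaseModel(disease=disease)
    in_scope = [
        s for s in stats if ontology.top_level_ancestors(s.term)
    ]  # terms outside the abnormality subtree cannot be clustered
    if not in_scope:
        return model

    seeds, leftovers = select_seeds(in_scope, params.n)
    if not seeds:
        # seedless fallback: keep the single best-TFIDF term, flagged
        best = min(in_scope, key=lambda s: (-s.tfidf, s.term))
        model.candidates = {best.term}
        model.provenance[best.term] = "fallback"
        return model

    stats_by_term = {s.term: s for s in in_scope}
    groups = ontology.top_level_groups(seeds)
    leftover_groups = (
        ontology.top_level_groups(leftovers) if leftovers else {}
    )
    for top in sorted(groups):
        subset = min_density_subset(ontology, groups[top])
        for t in subset:
            model.candidates.add(t)
            model.provenance[t] = "seed-subset"
        group_leftovers = [
            stats_by_term[t] for t in sorted(leftover_groups.get(top, ()))
        ]
        if not group_leftovers:
            continue
        seed_density = (
            density(ontology, subset) if len(subset) >= 2 else 0.0
        )
        for t in extend_candidates(
            ontology, subset, seed_density, group_leftovers, params.m, params.e
        ):
            if t not in model.candidates:
                model.candidates.add(t)
                model.provenance[t] = "density-extended"
    return model


def run_filter(
    ontology: Ontology,
    corpus: DiseaseCorpus,
    ic_table: ICTable,
    params: FilterParams,
    per_category_params: Mapping[str, FilterParams] | None = None,
    category_map: Mapping[str, str] | None = None,
    stats: Sequence[TermStats] | None = None,
) -> dict[str, DiseaseModel]:
    """Run the full filter for every disease in the corpus.

    ``per_category_params`` overrides the global ``params`` for diseases
    whose category (via ``category_map``) is present in the mapping.
    Diseases with no recognized terms yield an empty, flagged model.
    Precomputed ``stats`` may be passed to avoid recomputation.
    """
    if stats is None:
        stats = compute_stats(corpus, ic_table)
    by_disease: dict[str, list[TermStats]] = {}
    for s in stats:
        by_disease.setdefault(s.disease, []).append(s)

    models: dict[str, DiseaseModel] = {}
    for disease in sorted(corpus.disease_abstracts):
        disease_stats = by_disease.get(disease)
        if not disease_stats:
            logger.warning("disease %s has no recognized terms", disease)
            models[disease] = DiseaseModel(disease=disease)
            continue
        p = params
        if per_category_params and category_map and disease in category_map:
            p = per_category_params.get(category_map[disease], params)
        models[disease] = _filter_disease(ontology, disease_stats, p)
    return models


def models_to_frame(models: Mapping[str, DiseaseModel]) -> pd.DataFrame:
    rows = [
        (d, t, m.provenance.get(t, ""))
        for d, m in sorted(models.items())
        for t in sorted(m.candidates)
    ]
    return pd.DataFrame(rows, columns=["disease_id", "term_id", "provenance"])


# ---------------------------------------------------------------------------
# Evaluation and parameter learning
# ---------------------------------------------------------------------------


def _subsumption_matching_size(
    ontology: Ontology, model_terms: set[TermId], gold_terms: set[TermId]
) -> int:
    from .similarity import max_subsumption_matching

    return max_subsumption_matching(ontology, model_terms, gold_terms)


def evaluate(
    models: Mapping[str, DiseaseModel],
    gold: Mapping[str, set[TermId]],
    match_mode: str = "exact",
    ontology: Ontology | None = None,
) -> EvaluationResult:
    """Micro-averaged TP/FP/FN of models against gold annotations.

    In "subsumption" mode a model term matches a gold term when they are
    equal or one subsumes the other; matches are counted through a maximum
    bipartite matching so each term is credited at most once.
    """
    if match_mode not in ("exact", "subsumption"):
        raise ValueError(f"unknown match_mode {match_mode!r}")
    if match_mode == "subsumption" and ontology is None:
        raise ValueError("subsumption mode requires an ontology")
    per_disease: dict[str, EvaluationResult] = {}
    tot_tp = tot_fp = tot_fn = 0
    for disease in sorted(gold):
        if disease not in models:
            raise KeyError(f"gold disease {disease} absent from models")
        m_terms = set(models[disease].candidates)
        g_terms = set(gold[disease])
        if match_mode == "exact":
            tp = len(m_terms & g_terms)
        else:
            tp = _subsumption_matching_size(ontology, m_terms, g_terms)
        fp = len(m_terms) - tp
        fn = len(g_terms) - tp
        per_disease[disease] = EvaluationResult.from_counts(tp, fp, fn)
        tot_tp += tp
        tot_fp += fp
        tot_fn += fn
    result = EvaluationResult.from_counts(tot_tp, tot_fp, tot_fn)
    result.per_disease = per_disease
    return result


@dataclass(frozen=True)
class LearnedParams:
    params: FilterParams
    objective: float


def learn_parameters(
    ontology: Ontology,
    corpus: DiseaseCorpus,
    ic_table: ICTable,
    gold: Mapping[str, set[TermId]],
    category_map: Mapping[str, str],
    grid: Mapping[str, Sequence[float]],
    objective: str = "f_score",
    match_mode: str = "exact",
) -> dict[str, LearnedParams]:
    """Per-category exhaustive grid search maximizing the objective.

    ``grid`` holds candidate values for "n", "m" and "e".  For each
    category the objective (micro F-score or precision) is evaluated on
    that category's gold diseases at every grid point; ties resolve to the
    smallest n, then m, then e.  Categories with no gold disease are
    skipped with a warning.
    """
    if objective not in ("f_score", "precision"):
        raise ValueError(f"unknown objective {objective!r}")
    for key in ("n", "m", "e"):
        if not grid.get(key):
            raise ValueError(f"grid must provide values for {key!r}")
    stats = compute_stats(corpus, ic_table)
    by_disease: dict[str, list[TermStats]] = {}
    for s in stats:
        by_disease.setdefault(s.disease, []).append(s)
    categories = sorted(set(category_map.values()))
    learned: dict[str, LearnedParams] = {}
    for category in categories:
        diseases = sorted(
            d for d in gold if category_map.get(d) == category
        )
        if not diseases:
            logger.warning("category %s has no gold disease; skipped", category)
            continue
        cat_gold = {d: gold[d] for d in diseases}
        best: LearnedParams | None = None
        for n in sorted(grid["n"]):
            for m in sorted(grid["m"]):
                for e in sorted(grid["e"]):
                    params = FilterParams(n=n, m=m, e=e)
                    models = {
                        d: (
                            _filter_disease(ontology, by_disease[d], params)
                            if by_disease.get(d)
                            else DiseaseModel(disease=d)
                        )
                        for d in diseases
                    }
                    res = evaluate(
                        models, cat_gold, match_mode=match_mode, ontology=ontology
                    )
                    score = getattr(res, objective)
                    if best is None or score > best.objective:
                        best = LearnedParams(params=params, objective=score)
        learned[category] = best
    return learned
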