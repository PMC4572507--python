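"""Phenotypic overlap between annotation sets.

Two complementary measures:

* **Subsumption-extended Jaccard** — the classic |intersection| / |union|,
  except a term of one set may match a term of the other not only on
  equality but also when one subsumes the other (is an ancestor at any
  distance).  Matched pairs are counted through a maximum bipartite
  matching so each term is consumed at most once, which keeps the index
  within [0, 1] and reduces it to the plain Jaccard when only exact
  matches exist.

* **Symmetric Resnik-style similarity** — for each term of one disease the
  best match in the other is scored by the information content of their
  most informative common ancestor (MICA); directed scores are averaged
  over query terms and the two directions are averaged to symmetrize:
  sim(D1, D2) = 1/2 sim(D1->D2) + 1/2 sim(D2->D1).

For disease-level similarity the IC table is conventionally computed from
disease annotation frequencies (proportion of diseases annotated with the
term or a descendant), not from the abstract-level frequencies used by the
TFIDFIC filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .ontology import ICTable, Ontology, TermId

__all__ = [
    "AnnotationSet",
    "SimilarityMatrix",
    "extended_jaccard",
    "max_subsumption_matching",
    "mica_ic",
    "sim_directed",
    "sim_symmetric",
    "pairwise_similarity",
]


@dataclass(frozen=True)
class AnnotationSet:
    """A disease and its set of phenotype term annotations."""

    owner: str
    terms: frozenset[TermId]

    @classmethod
    def of(cls, owner: str, terms: Iterable[TermId]) -> "AnnotationSet":
        return cls(owner=owner, terms=frozenset(terms))


def max_subsumption_matching(
    ontology: Ontology, a_terms: Iterable[TermId], b_terms: Iterable[TermId]
) -> int:
    """Size of a maximum bipartite matching under the subsumption relation.

    A pair (a, b) is matchable iff a == b or one is an ancestor of the
    other at any distance.
    """
    a_list = sorted(set(a_terms))
    b_list = sorted(set(b_terms))
    if not a_list or not b_list:
        return 0
    b_closure = {
        b: ontology.ancestors(b, reflexive=True) | ontology.descendants(b)
        for b in b_list
    }
    rows, cols = [], []
    for i, a in enumerate(a_list):
        for j, b in enumerate(b_list):
            if a in b_closure[b]:
                rows.append(i)
                cols.append(j)
    if not rows:
        return 0
    biadj = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(a_list), len(b_list)),
    )
    matching = maximum_bipartite_matching(biadj, perm_type="column")
    return int((matching >= 0).sum())


def extended_jaccard(
    ontology: Ontology, a: AnnotationSet | Iterable[TermId], b: AnnotationSet | Iterable[TermId]
) -> float:
    """Jaccard index with subsumption-aware matching.

    J = |M| / (|A| + |B| - |M|) where M is a maximum matching of terms
    related by equality or subsumption.  Two empty sets give 0 by
    convention.
    """
    a_terms = set(a.terms if isinstance(a, AnnotationSet) else a)
    b_terms = set(b.terms if isinstance(b, AnnotationSet) else b)
    if not a_terms and not b_terms:
        return 0.0
    m = max_subsumption_matching(ontology, a_terms, b_terms)
    return m / (len(a_terms) + len(b_terms) - m)


def mica_ic(
    ontology: Ontology,
    ic_table: ICTable,
    t1: TermId,
    t2: TermId,
    _memo: dict | None = None,
) -> float:
    """IC of the most informative common ancestor of two terms.

    Ancestors with undefined IC (never annotated) are skipped; if no
    common ancestor is annotated the score is 0, the IC of a vacuous
    root-level match.
    """
    if _memo is not None:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        if key in _memo:
            return _memo[key]
    common = ontology.ancestors(t1, reflexive=True) & ontology.ancestors(
        t2, reflexive=True
    )
    ic = ic_table.ic
    best = 0.0
    for t in common:
        v = ic.get(t, 0.0)
        if v != np.inf and v > best:
            best = v
    if _memo is not None:
        _memo[key] = best
    return best


def sim_directed(
    ontology: Ontology,
    ic_table: ICTable,
    d1: AnnotationSet | Iterable[TermId],
    d2: AnnotationSet | Iterable[TermId],
    _memo: dict | None = None,
) -> float:
    """Average best-match MICA information content of d1's terms in d2."""
    t1 = sorted(d1.terms if isinstance(d1, AnnotationSet) else set(d1))
    t2 = sorted(d2.terms if isinstance(d2, AnnotationSet) else set(d2))
    if not t1:
        raise ValueError("query annotation set must be non-empty")
    if not t2:
        return 0.0
    total = 0.0
    for s in t1:
        total += max(mica_ic(ontology, ic_table, s, t, _memo) for t in t2)
    return total / len(t1)


def sim_symmetric(
    ontology: Ontology,
    ic_table: ICTable,
    d1: AnnotationSet | Iterable[TermId],
    d2: AnnotationSet | Iterable[TermId],
    _memo: dict | None = None,
) -> float:
    """Symmetrized semantic similarity: the mean of the two directions."""
    t1 = set(d1.terms if isinstance(d1, AnnotationSet) else d1)
    t2 = set(d2.terms if isinstance(d2, AnnotationSet) else d2)
    if not t1 or not t2:
        raise ValueError("both annotation sets must be non-empty")
    return 0.5 * sim_directed(ontology, ic_table, t1, t2, _memo) + 0.5 * sim_directed(
        ontology, ic_table, t2, t1, _memo
    )


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise disease-similarity matrix with its id order."""

    ids: list[str]
    values: np.ndarray

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            (self.ids[i], self.ids[j], float(self.values[i, j]))
            for i in range(len(self.ids))
            for j in range(i + 1, len(self.ids))
        ]
        return pd.DataFrame(rows, columns=["disease_a", "disease_b", "score"])

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_long_tsv(self, path_or_buf) -> None:
        self.to_long_frame().to_csv(path_or_buf, sep="\t", index=False)

    def write_square_tsv(self, path_or_buf) -> None:
        self.to_square_frame().to_csv(path_or_buf, sep="\t")


def pairwise_similarity(
    ontology: Ontology, ic_table: ICTable, sets: Sequence[AnnotationSet]
) -> SimilarityMatrix:
    """Symmetric similarity for all unordered pairs of annotation sets."""
    ids = [s.owner for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate annotation-set owners")
    for s in sets:
        if not s.terms:
            raise ValueError(f"annotation set for {s.owner} is empty")
    n = len(sets)
    values = np.zeros((n, n))
    memo: dict = {}
    for i in range(n):
        values[i, i] = sim_symmetric(ontology, ic_table, sets[i], sets[i], memo)
        for j in range(i + 1, n):
            v = sim_symmetric(ontology, ic_table, sets[i], sets[j], memo)
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(ids=ids, values=values)
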