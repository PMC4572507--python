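"""Ontology handling: OBO parsing, DAG operations, and information content.

The ontology is a rooted DAG of phenotype terms linked by is-a edges.  Terms
carry a primary label and any number of synonyms; both feed the concept
recognizer.  On top of the graph this module provides the operations the
annotation pipeline needs: ancestor closures, grouping by top-level
abnormality category, undirected shortest paths (the "cost" used by the
density filter), corpus-driven term frequencies with their information
content IC(t) = -log p(t), and the most informative common ancestor (MICA)
of two terms.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx
import obonet
import pandas as pd

TermId = str

__all__ = [
    "TermId",
    "OntologyTerm",
    "Ontology",
    "ICTable",
    "OntologyError",
    "UnknownTermError",
    "parse_obo",
    "term_frequencies",
    "mica",
]


class OntologyError(ValueError):
    """Structural problem: cycle, missing parent, ambiguous root."""


class UnknownTermError(KeyError):
    """A term id was not found in the ontology."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology class with its lexical forms and direct parents."""

    id: TermId
    label: str
    synonyms: tuple[str, ...] = ()
    parents: tuple[TermId, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyError("term id must be non-empty")
        if not self.label:
            raise OntologyError(f"term {self.id} has an empty label")


class Ontology:
    """A rooted is-a DAG of :class:`OntologyTerm`.

    Parameters
    ----------
    terms
        The term records.  Every parent referenced must itself be present.
    root
        Id of the single root.  If omitted, the unique parentless term is
        used; multiple parentless terms without an explicit root are an
        error.
    abnormality_root
        The sub-root whose *children* are the top-level phenotype
        categories (organ systems).  Defaults to the child of the root
        labelled "phenotypic abnormality" if one exists, otherwise the
        root itself.  Configurable because flat toy ontologies may hang
        categories directly off the root.
    """

    def __init__(
        self,
        terms: Iterable[OntologyTerm],
        root: TermId | None = None,
        abnormality_root: TermId | None = None,
    ) -> None:
        self._terms: dict[TermId, OntologyTerm] = {}
        for t in terms:
            if t.id in self._terms:
                raise OntologyError(f"duplicate term id {t.id}")
            self._terms[t.id] = t

        graph = nx.DiGraph()  # edges child -> parent
        graph.add_nodes_from(self._terms)
        for t in self._terms.values():
            for p in t.parents:
                if p not in self._terms:
                    raise OntologyError(f"term {t.id} has missing parent {p}")
                graph.add_edge(t.id, p)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            pass
        else:
            u, v = cycle[0][:2]
            raise OntologyError(f"is-a cycle detected (contains edge {u} -> {v})")
        self._graph = graph
        self._undirected = graph.to_undirected(as_view=True)

        roots = [tid for tid in self._terms if graph.out_degree(tid) == 0]
        if root is not None:
            if root not in self._terms:
                raise UnknownTermError(root)
            self._root = root
        elif not self._terms:
            self._root = None  # degenerate empty ontology
        elif len(roots) == 1:
            self._root = roots[0]
        else:
            raise OntologyError(
                f"expected a single parentless root, found {sorted(roots)}; "
                "pass root= explicitly"
            )
        if self._terms and not all(
            nx.has_path(self._undirected, tid, self._root) for tid in self._terms
        ):
            raise OntologyError("ontology is not connected to the root")

        if abnormality_root is not None:
            if abnormality_root not in self._terms:
                raise UnknownTermError(abnormality_root)
            self._abnormality_root = abnormality_root
        else:
            self._abnormality_root = self._root
            for child in (self.children(self._root) if self._root else ()):
                if self._terms[child].label.strip().lower() == "phenotypic abnormality":
                    self._abnormality_root = child
                    break

        self._depth_cache: dict[TermId, int] = {}
        self._bfs_cache: dict[TermId, dict[TermId, int]] = {}

    # -- basic container protocol -------------------------------------------------

    def __contains__(self, tid: TermId) -> bool:
        return tid in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[TermId]:
        return iter(self._terms)

    def __repr__(self) -> str:
        return f"Ontology({len(self)} terms, root={self._root!r})"

    @property
    def root(self) -> TermId:
        return self._root

    @property
    def abnormality_root(self) -> TermId:
        return self._abnormality_root

    def term(self, tid: TermId) -> OntologyTerm:
        try:
            return self._terms[tid]
        except KeyError:
            raise UnknownTermError(tid) from None

    def label(self, tid: TermId) -> str:
        return self.term(tid).label

    # -- graph operations ---------------------------------------------------------

    def parents(self, tid: TermId) -> set[TermId]:
        self.term(tid)
        return set(self._graph.successors(tid))

    def children(self, tid: TermId) -> set[TermId]:
        self.term(tid)
        return set(self._graph.predecessors(tid))

    def ancestors(self, tid: TermId, reflexive: bool = False) -> set[TermId]:
        """Transitive closure over is-a edges toward the root."""
        self.term(tid)
        anc = nx.descendants(self._graph, tid)  # edges point child -> parent
        if reflexive:
            anc.add(tid)
        return anc

    def descendants(self, tid: TermId, reflexive: bool = False) -> set[TermId]:
        self.term(tid)
        desc = nx.ancestors(self._graph, tid)
        if reflexive:
            desc.add(tid)
        return desc

    def is_ancestor(self, anc: TermId, desc: TermId) -> bool:
        """True iff *anc* is a (proper) ancestor of *desc*."""
        return anc in self.ancestors(desc)

    def subsumes_or_equal(self, t1: TermId, t2: TermId) -> bool:
        """True iff t1 = t2 or one is an ancestor of the other (any distance)."""
        return t1 == t2 or self.is_ancestor(t1, t2) or self.is_ancestor(t2, t1)

    @property
    def top_level_terms(self) -> set[TermId]:
        """Children of the abnormality root: the organ-system categories."""
        return self.children(self._abnormality_root)

    def top_level_ancestors(self, tid: TermId) -> set[TermId]:
        return self.ancestors(tid, reflexive=True) & self.top_level_terms

    def top_level_groups(
        self, terms: Iterable[TermId]
    ) -> dict[TermId, set[TermId]]:
        """Group *terms* by their top-level category ancestors.

        A term descending from several top-level categories is placed in
        every such group; downstream consumers deduplicate.  A term outside
        the abnormality subtree has no top-level ancestor and is an error.
        """
        groups: dict[TermId, set[TermId]] = {}
        for tid in terms:
            tops = self.top_level_ancestors(tid)
            if not tops:
                raise OntologyError(
                    f"term {tid} is not a descendant of a top-level category "
                    f"under {self._abnormality_root}"
                )
            for top in tops:
                groups.setdefault(top, set()).add(tid)
        return groups

    def shortest_path_length(self, t1: TermId, t2: TermId) -> int:
        """Minimum number of is-a edges connecting two terms, undirected."""
        self.term(t1)
        self.term(t2)
        # cache full BFS per source: pairwise distance matrices reuse sources
        if t1 not in self._bfs_cache:
            self._bfs_cache[t1] = dict(
                nx.single_source_shortest_path_length(self._undirected, t1)
            )
        return self._bfs_cache[t1][t2]

    def depth(self, tid: TermId) -> int:
        """Length of the longest directed path from *tid* up to the root."""
        self.term(tid)
        cache = self._depth_cache
        # iterative DFS to avoid recursion limits on deep chains
        stack = [tid]
        while stack:
            t = stack[-1]
            if t in cache:
                stack.pop()
                continue
            ps = self.parents(t)
            missing = [p for p in ps if p not in cache]
            if missing:
                stack.extend(missing)
                continue
            cache[t] = 1 + max((cache[p] for p in ps), default=-1)
            stack.pop()
        return cache[tid]


@dataclass
class ICTable:
    """Term frequencies p(t) and information content IC(t) = -log p(t).

    Frequencies are computed under ancestor propagation: an item annotated
    with a term implicitly carries all of the term's ancestors, so p is
    monotonically non-decreasing toward the root.  Terms never reached by
    any annotation have p = 0; their IC is recorded as +inf and they are
    listed in ``unannotated`` (they can never win a MICA comparison and are
    skipped by TFIDFIC).
    """

    frequency: dict[TermId, float]
    ic: dict[TermId, float]
    n_items: int
    log_base: float | None = None  # None = natural log
    unannotated: set[TermId] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        terms = sorted(self.frequency)
        return pd.DataFrame(
            {
                "term_id": terms,
                "frequency": [self.frequency[t] for t in terms],
                "ic": [self.ic[t] for t in terms],
            }
        )

    def write_tsv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, sep="\t", index=False)


def _log(x: float, base: float | None) -> float:
    return math.log(x) if base is None else math.log(x, base)


def term_frequencies(
    ontology: Ontology,
    annotations: Mapping[str, Iterable[TermId]],
    n_items: int | None = None,
    log_base: float | None = None,
) -> ICTable:
    """Annotation frequency and IC of every ontology term.

    p(t) is the fraction of items annotated with t *or any descendant* of t
    (each item counted at most once per term), so explicit annotation sets
    are first closed under the ancestor relation.  ``n_items`` defaults to
    the number of annotated items but may be larger, e.g. when only a
    subset of a corpus carries annotations.
    """
    if n_items is None:
        n_items = len(annotations)
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    counts: Counter[TermId] = Counter()
    for item_terms in annotations.values():
        closure: set[TermId] = set()
        for t in item_terms:
            closure.update(ontology.ancestors(t, reflexive=True))
        counts.update(closure)
    frequency: dict[TermId, float] = {}
    ic: dict[TermId, float] = {}
    unannotated: set[TermId] = set()
    for tid in ontology:
        p = counts.get(tid, 0) / n_items
        frequency[tid] = p
        if p > 0.0:
            ic[tid] = max(0.0, -_log(p, log_base))
        else:
            ic[tid] = math.inf
            unannotated.add(tid)
    return ICTable(
        frequency=frequency,
        ic=ic,
        n_items=n_items,
        log_base=log_base,
        unannotated=unannotated,
    )


def mica(ontology: Ontology, ic_table: ICTable, t1: TermId, t2: TermId) -> TermId:
    """Most informative common ancestor of two terms (reflexive).

    Among common ancestors with finite IC, returns the one maximizing IC;
    ties broken by greatest depth (most specific), then smallest id.
    Unannotated terms (IC undefined) are excluded from the maximization.
    """
    common = ontology.ancestors(t1, reflexive=True) & ontology.ancestors(
        t2, reflexive=True
    )
    candidates = [t for t in common if t not in ic_table.unannotated]
    if not candidates:
        raise ValueError(
            f"no common ancestor of {t1} and {t2} has defined IC; "
            "was the IC table computed on this ontology?"
        )
    return max(
        candidates,
        key=lambda t: (ic_table.ic[t], ontology.depth(t), _neg_lex(t)),
    )


class _neg_lex(str):
    """Wrapper inverting lexicographic order so max() picks the smallest id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)


def write_obo(ontology: Ontology, path_or_buf) -> None:
    """Write the ontology as minimal OBO 1.4 [Term] stanzas."""
    own = not hasattr(path_or_buf, "write")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write("format-version: 1.4\n")
        for tid in sorted(ontology):
            term = ontology.term(tid)
            fh.write(f"\n[Term]\nid: {term.id}\nname: {term.label}\n")
            for syn in term.synonyms:
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for parent in term.parents:
                fh.write(f"is_a: {parent} ! {ontology.label(parent)}\n")
    finally:
        if own:
            fh.close()


_SYNONYM_RE = re.compile(r'"(.*)"')


def parse_obo(
    source: str | IO[str],
    root: TermId | None = None,
    abnormality_root: TermId | None = None,
) -> Ontology:
    """Parse an OBO 1.2/1.4 file (path or text stream) into an Ontology.

    Obsolete terms are dropped, synonyms of every scope are retained, only
    is-a relationships are loaded, and acyclicity is verified.
    """
    graph = obonet.read_obo(source, ignore_obsolete=True)
    terms = []
    for tid, data in graph.nodes(data=True):
        if "name" not in data:
            # node created only as an is_a target of some stanza
            raise OntologyError(f"is_a target {tid} has no [Term] stanza")
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.search(raw)
            if m and m.group(1):
                synonyms.append(m.group(1))
        parents = tuple(
            v for _, v, key in graph.out_edges(tid, keys=True) if key == "is_a"
        )
        terms.append(
            OntologyTerm(
                id=tid,
                label=data["name"],
                synonyms=tuple(synonyms),
                parents=parents,
            )
        )
    return Ontology(terms, root=root, abnormality_root=abnormality_root)
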