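"""Disease-tagged abstract corpora: MeSH filtering, mention attachment, and
synthetic corpus generation.

A corpus associates each whitelisted disease descriptor with the abstracts
indexed under it, and each abstract with the set of ontology terms the
recognizer found in it.  Term presence is abstract-level: five mentions of
a term in one abstract count once.

The synthetic generator emulates the statistical structure the filtering
algorithm assumes: each disease has a planted set of phenotype terms
concentrated in one or two top-level organ-system categories, its abstracts
mention planted-term labels (or synonyms) at a controlled per-abstract
probability, and scattered off-plant noise terms appear at a controlled
Poisson rate.  The planted sets are the ground truth for recovery tests.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .concept_recognition import Mention
from .ontology import Ontology, OntologyTerm, TermId

__all__ = [
    "AbstractRecord",
    "DiseaseCorpus",
    "SyntheticTruth",
    "filter_by_mesh",
    "attach_mentions",
    "generate_synthetic",
    "synthetic_ontology",
    "read_abstracts_jsonl",
    "write_abstracts_jsonl",
    "read_abstracts_tsv",
    "write_abstracts_tsv",
]

logger = logging.getLogger(__name__)

# Filler vocabulary for synthetic abstracts: generic methods-speak that can
# never collide with the toy lexicon (toy labels are single coined tokens).
_FILLER = (
    "patients study cohort reported clinical observed significant analysis "
    "treatment results followup baseline outcome measured association "
    "evaluated prevalence diagnosis therapy response controls"
).split()


@dataclass(frozen=True)
class AbstractRecord:
    """One literature abstract with its MeSH disease descriptors."""

    abstract_id: str
    title: str
    body: str
    mesh_descriptors: frozenset[str] = frozenset()

    @property
    def has_valid_body(self) -> bool:
        return bool(self.body.strip())


@dataclass
class DiseaseCorpus:
    """Disease -> abstracts mapping plus per-abstract recognized term sets."""

    disease_abstracts: dict[str, set[str]] = field(default_factory=dict)
    abstracts: dict[str, AbstractRecord] = field(default_factory=dict)
    raw_mentions: dict[str, set[TermId]] = field(default_factory=dict)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_abstracts)

    def disease_terms(self, disease: str) -> set[TermId]:
        """Union of recognized terms over the disease's abstracts."""
        out: set[TermId] = set()
        for aid in self.disease_abstracts.get(disease, ()):
            out.update(self.raw_mentions.get(aid, ()))
        return out

    def abstract_annotations(self) -> dict[str, set[TermId]]:
        """abstract_id -> recognized term set, for IC estimation."""
        return {aid: set(self.raw_mentions.get(aid, set())) for aid in self.abstracts}


def filter_by_mesh(
    records: Iterable[AbstractRecord], whitelist: Iterable[str]
) -> DiseaseCorpus:
    """Keep abstracts with a valid body and >= 1 whitelisted descriptor.

    A kept abstract is assigned to *every* whitelisted descriptor it
    carries.  Whitelist diseases matching no abstract are absent from the
    corpus (logged); ``n_diseases`` counts only retained diseases.
    """
    wl = set(whitelist)
    if not wl:
        raise ValueError("whitelist must be non-empty")
    corpus = DiseaseCorpus()
    for rec in records:
        if not rec.has_valid_body:
            continue
        hits = rec.mesh_descriptors & wl
        if not hits:
            continue
        corpus.abstracts[rec.abstract_id] = rec
        for d in hits:
            corpus.disease_abstracts.setdefault(d, set()).add(rec.abstract_id)
    missing = wl - set(corpus.disease_abstracts)
    if missing:
        logger.warning(
            "%d whitelist disease(s) matched no abstract and were dropped", len(missing)
        )
    return corpus


def attach_mentions(corpus: DiseaseCorpus, mentions: Iterable[Mention]) -> DiseaseCorpus:
    """Populate per-abstract term sets from recognizer output (deduplicated).

    Mentions referring to abstracts outside the corpus are skipped with a
    warning.  Returns the (mutated) corpus for chaining.
    """
    n_orphans = 0
    for m in mentions:
        if m.abstract_id not in corpus.abstracts:
            n_orphans += 1
            continue
        corpus.raw_mentions.setdefault(m.abstract_id, set()).add(m.term)
    if n_orphans:
        warnings.warn(f"skipped {n_orphans} mention(s) with unknown abstract ids")
    return corpus


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Planted disease -> term-set ground truth with the generator record."""

    planted: dict[str, set[TermId]]
    params_used: dict

    def to_json(self, path_or_buf: str | IO[str]) -> None:
        payload = {
            "planted": {d: sorted(ts) for d, ts in self.planted.items()},
            "params_used": self.params_used,
        }
        if hasattr(path_or_buf, "write"):
            json.dump(payload, path_or_buf, indent=1)
        else:
            with open(path_or_buf, "w") as fh:
                json.dump(payload, fh, indent=1)


def synthetic_ontology(
    n_top_level: int = 8,
    terms_per_group: int = 24,
    seed: int = 0,
    p_extra_parent: float = 0.08,
) -> Ontology:
    """A toy HPO-like DAG for tests and synthetic corpora.

    Structure: root <- "phenotypic abnormality" <- ``n_top_level`` category
    terms, each carrying a random tree of ``terms_per_group`` terms (1-3
    children per node) with occasional extra is-a edges inside the same
    category subtree, producing diamonds.  Labels are unique coined tokens
    ("phenNNNN") with one synonym each ("synNNNN") so dictionary matching
    on them is unambiguous.
    """
    rng = np.random.default_rng(seed)
    terms: list[OntologyTerm] = [
        OntologyTerm("TOY:0000001", "all"),
        OntologyTerm("TOY:0000002", "phenotypic abnormality", parents=("TOY:0000001",)),
    ]
    counter = 2

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"TOY:{counter:07d}"

    for g in range(n_top_level):
        top_id = new_id()
        terms.append(
            OntologyTerm(top_id, f"categ{g:02d}", parents=("TOY:0000002",))
        )
        subtree: list[str] = [top_id]
        for _ in range(terms_per_group):
            tid = new_id()
            parent = subtree[int(rng.integers(len(subtree)))]
            parents = [parent]
            if len(subtree) > 2 and rng.random() < p_extra_parent:
                extra = subtree[int(rng.integers(len(subtree)))]
                if extra != parent:
                    parents.append(extra)
            idx = counter - 2
            terms.append(
                OntologyTerm(
                    tid,
                    f"phen{idx:04d}",
                    synonyms=(f"syn{idx:04d}",),
                    parents=tuple(parents),
                )
            )
            subtree.append(tid)
    return Ontology(terms, root="TOY:0000001", abnormality_root="TOY:0000002")


def generate_synthetic(
    ontology: Ontology,
    n_diseases: int = 30,
    terms_per_disease: int = 8,
    abstracts_per_disease: int = 20,
    mention_prob: float = 0.8,
    noise_rate: float = 2.0,
    n_categories: int = 5,
    seed: int = 0,
    synonym_prob: float = 0.3,
) -> tuple[list[AbstractRecord], SyntheticTruth, dict[str, set[str]]]:
    """Generate a disease-tagged corpus with planted phenotype models.

    Each disease draws its planted terms from the leaf terms of one or two
    top-level categories (diseases affect few major organ systems), and
    each of its abstracts mentions every planted term independently with
    probability ``mention_prob`` (using the term's synonym instead of its
    label with probability ``synonym_prob``), plus Poisson(``noise_rate``)
    off-plant terms drawn uniformly from the remaining leaf terms.
    Disease categories for network coloring are assigned round-robin.
    Deterministic given ``seed``.
    """
    if min(n_diseases, terms_per_disease, abstracts_per_disease, n_categories) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)

    tops = sorted(ontology.top_level_terms)
    leaves_by_top: dict[TermId, list[TermId]] = {}
    all_leaves: list[TermId] = []
    for top in tops:
        leaves = sorted(
            t for t in ontology.descendants(top, reflexive=False)
            if not ontology.children(t)
        )
        leaves_by_top[top] = leaves
        all_leaves.extend(leaves)
    if len(all_leaves) < terms_per_disease:
        raise ValueError(
            f"ontology has {len(all_leaves)} leaf terms, "
            f"fewer than terms_per_disease={terms_per_disease}"
        )

    records: list[AbstractRecord] = []
    planted: dict[str, set[TermId]] = {}
    category_map: dict[str, set[str]] = {}

    for i in range(n_diseases):
        disease = f"MESH:D{i:04d}"
        category_map[disease] = {f"CAT{i % n_categories:02d}"}

        n_groups = 1 + int(rng.random() < 0.5)
        chosen = list(rng.choice(len(tops), size=min(n_groups, len(tops)), replace=False))
        pool = sorted({t for g in chosen for t in leaves_by_top[tops[g]]})
        while len(pool) < terms_per_disease:
            extra = int(rng.integers(len(tops)))
            if extra not in chosen:
                chosen.append(extra)
                pool = sorted({t for g in chosen for t in leaves_by_top[tops[g]]})
        idx = rng.choice(len(pool), size=terms_per_disease, replace=False)
        disease_terms = {pool[j] for j in idx}
        planted[disease] = disease_terms
        off_plant = [t for t in all_leaves if t not in disease_terms]

        for j in range(abstracts_per_disease):
            phrases: list[str] = []
            for t in sorted(disease_terms):
                if rng.random() < mention_prob:
                    term = ontology.term(t)
                    if term.synonyms and rng.random() < synonym_prob:
                        phrases.append(term.synonyms[0])
                    else:
                        phrases.append(term.label)
            n_noise = int(rng.poisson(noise_rate)) if noise_rate > 0 else 0
            for _ in range(min(n_noise, len(off_plant))):
                phrases.append(ontology.label(off_plant[int(rng.integers(len(off_plant)))]))
            # interleave phrases with filler so matches sit in running text
            words: list[str] = []
            for p in phrases:
                words.extend(rng.choice(_FILLER, size=2))
                words.append(p)
            words.extend(rng.choice(_FILLER, size=3))
            records.append(
                AbstractRecord(
                    abstract_id=f"A{i:04d}x{j:04d}",
                    title=f"Study {j} of disease {i}",
                    body=" ".join(words) + ".",
                    mesh_descriptors=frozenset({disease}),
                )
            )

    truth = SyntheticTruth(
        planted=planted,
        params_used={
            "n_diseases": n_diseases,
            "terms_per_disease": terms_per_disease,
            "abstracts_per_disease": abstracts_per_disease,
            "mention_prob": mention_prob,
            "noise_rate": noise_rate,
            "n_categories": n_categories,
            "synonym_prob": synonym_prob,
            "seed": seed,
        },
    )
    return records, truth, category_map


# ---------------------------------------------------------------------------
# Abstract record I/O: line-delimited JSON and 4-column TSV
# ---------------------------------------------------------------------------


def write_abstracts_jsonl(records: Iterable[AbstractRecord], path_or_buf) -> None:
    """One JSON object per line: {"id", "title", "abstract", "mesh"}."""
    own = not hasattr(path_or_buf, "write")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "id": rec.abstract_id,
                        "title": rec.title,
                        "abstract": rec.body,
                        "mesh": sorted(rec.mesh_descriptors),
                    }
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()


def read_abstracts_jsonl(path_or_buf) -> list[AbstractRecord]:
    own = not hasattr(path_or_buf, "read")
    fh = open(path_or_buf) if own else path_or_buf
    try:
        records = []
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            records.append(
                AbstractRecord(
                    abstract_id=str(obj["id"]),
                    title=obj.get("title", ""),
                    body=obj.get("abstract", ""),
                    mesh_descriptors=frozenset(obj.get("mesh", [])),
                )
            )
        return records
    finally:
        if own:
            fh.close()


def write_abstracts_tsv(records: Iterable[AbstractRecord], path_or_buf) -> None:
    """4-column TSV: id, title, abstract, semicolon-joined MeSH ids."""
    df = pd.DataFrame(
        [
            (r.abstract_id, r.title, r.body, ";".join(sorted(r.mesh_descriptors)))
            for r in records
        ],
        columns=["id", "title", "abstract", "mesh"],
    )
    df.to_csv(path_or_buf, sep="\t", index=False)


def read_abstracts_tsv(path_or_buf) -> list[AbstractRecord]:
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, keep_default_na=False)
    return [
        AbstractRecord(
            abstract_id=row["id"],
            title=row["title"],
            body=row["abstract"],
            mesh_descriptors=frozenset(m for m in row["mesh"].split(";") if m),
        )
        for _, row in df.iterrows()
    ]
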