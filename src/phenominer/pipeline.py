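"""End-to-end orchestration: corpus -> recognition -> models -> network.

Thin convenience layer over the individual modules, used by the CLI and by
scripted analyses.  Two distinct IC tables appear in the pipeline and are
kept separate on purpose: the *abstract-level* IC (term frequency among
recognized abstract annotations) feeds the TFIDFIC filter, while the
*disease-level* IC (proportion of diseases annotated with a term or a
descendant) feeds semantic similarity for the disease network.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from . import concept_recognition as cr
from .corpus import AbstractRecord, DiseaseCorpus, attach_mentions, filter_by_mesh
from .filtering import DiseaseModel, FilterParams, compute_stats, run_filter
from .network import CDN, build_cdn
from .ontology import ICTable, Ontology, term_frequencies
from .similarity import AnnotationSet, SimilarityMatrix, pairwise_similarity

__all__ = [
    "annotate_corpus",
    "abstract_level_ic",
    "disease_level_ic",
    "derive_models",
    "model_annotation_sets",
    "build_disease_network",
]


def annotate_corpus(
    ontology: Ontology,
    records: Iterable[AbstractRecord],
    whitelist: Iterable[str],
) -> DiseaseCorpus:
    """MeSH-filter the records and run concept recognition on every abstract."""
    corpus = filter_by_mesh(records, whitelist)
    index = cr.build_index(ontology)
    mentions = []
    for rec in corpus.abstracts.values():
        mentions.extend(cr.recognize_record(index, rec.abstract_id, rec.title, rec.body))
    return attach_mentions(corpus, mentions)


def abstract_level_ic(ontology: Ontology, corpus: DiseaseCorpus) -> ICTable:
    """IC from term frequencies among the corpus's recognized abstracts."""
    return term_frequencies(ontology, corpus.abstract_annotations())


def derive_models(
    ontology: Ontology,
    corpus: DiseaseCorpus,
    params: FilterParams,
    per_category_params: Mapping[str, FilterParams] | None = None,
    category_map: Mapping[str, str] | None = None,
) -> tuple[dict[str, DiseaseModel], ICTable]:
    """Run the TFIDF/density filter for every disease; returns models + IC."""
    ic_table = abstract_level_ic(ontology, corpus)
    stats = compute_stats(corpus, ic_table)
    models = run_filter(
        ontology,
        corpus,
        ic_table,
        params,
        per_category_params=per_category_params,
        category_map=category_map,
        stats=stats,
    )
    return models, ic_table


def model_annotation_sets(models: Mapping[str, DiseaseModel]) -> list[AnnotationSet]:
    """Non-empty disease models as annotation sets (empty models excluded)."""
    return [
        AnnotationSet.of(d, m.candidates)
        for d, m in sorted(models.items())
        if m.candidates
    ]


def disease_level_ic(
    ontology: Ontology, models: Mapping[str, DiseaseModel]
) -> ICTable:
    """IC from the proportion of diseases annotated with each term."""
    annotations = {d: set(m.candidates) for d, m in models.items() if m.candidates}
    return term_frequencies(ontology, annotations)


def build_disease_network(
    ontology: Ontology,
    models: Mapping[str, DiseaseModel],
    categories: Mapping[str, Iterable[str]],
    simcut: float = 2.0,
) -> tuple[CDN, SimilarityMatrix, ICTable]:
    """Pairwise symmetric similarity of all modeled diseases, thresholded."""
    sets = model_annotation_sets(models)
    ic_table = disease_level_ic(ontology, models)
    matrix = pairwise_similarity(ontology, ic_table, sets)
    cdn = build_cdn(matrix, categories, simcut)
    return cdn, matrix, ic_table
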