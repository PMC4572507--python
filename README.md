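# phenominer

Disease → phenotype annotation models mined from disease-tagged abstract
corpora, with semantic-similarity disease networks and randomization
tests.

Rare-disease informatics rests on curated phenotype annotations — e.g.
"Marfan syndrome is characterized by arachnodactyly" expressed as ontology
terms — but no comparable resource exists for most common diseases.
`phenominer` is a toolkit for deriving such annotations from literature:
given an ontology of phenotype terms (OBO), a corpus of abstracts tagged
with disease descriptors (MeSH-style), and a disease whitelist, it

1. **recognizes** term mentions by normalized dictionary lookup over
   labels and synonyms (greedy longest match, no negation handling);
2. **weights** each (disease, term) pair by TF·IDF with diseases as
   documents — TF(t,D) = number of D-abstracts mentioning t, IDF(t,D) =
   log(T_D / #diseases mentioning t) — and by the term's information
   content IC(t) = −log p(t), with p(t) the annotation frequency of t or
   any descendant;
3. **filters** each disease's terms with a three-parameter procedure
   (TFIDF seed threshold *n*, TFIDFIC prune threshold *m*, density margin
   *e*): seeds are grouped by top-level organ-system category, each group
   is reduced to its minimum-*density* subset (density = population SD of
   pairwise shortest-path lengths in the ontology), and pruned leftovers
   rejoin a group when they keep its density within *e*;
4. **compares** diseases by the subsumption-extended Jaccard index
   (ancestor/descendant pairs count as matches, via maximum bipartite
   matching) or by symmetric Resnik similarity, sim(D1,D2) =
   ½·sim(D1→D2) + ½·sim(D2→D1) with term pairs scored by the IC of their
   most informative common ancestor (MICA);
5. **assembles** a common-disease network (edge when similarity exceeds a
   cutoff `simcut`) and tests its agreement with an independent disease
   classification via the gray-edge fraction (GEF — the proportion of
   edges joining diseases that share no category) under degree-preserving
   edge randomization and under annotation randomization, with add-one
   empirical p-values.

A synthetic-data module generates toy ontologies and corpora with planted
disease models, so the entire pipeline is testable without any external
data. Parameter learning (per-category grid search against a gold
standard) and evaluation (precision/recall/F, exact or subsumption-aware)
are included.

## Worked example

```python
from phenominer import (
    FilterParams, evaluate, generate_synthetic, gray_edge_fraction,
    gef_significance, synthetic_ontology,
)
from phenominer import pipeline

ontology = synthetic_ontology(seed=7)
records, truth, _ = generate_synthetic(ontology, noise_rate=2.0, seed=7)
corpus = pipeline.annotate_corpus(ontology, records, sorted(truth.planted))
models, ic = pipeline.derive_models(ontology, corpus, FilterParams(n=5, m=5, e=1.0))
result = evaluate(models, truth.planted)
print(f"precision={result.precision:.3f} recall={result.recall:.3f} F={result.f_score:.3f}")

# label each disease by the organ systems its planted terms belong to
categories = {
    d: {ontology.label(top) for t in terms for top in ontology.top_level_ancestors(t)}
    for d, terms in truth.planted.items()
}
cdn, matrix, _ = pipeline.build_disease_network(ontology, models, categories, simcut=1.5)
stats = gray_edge_fraction(cdn)
print(f"CDN: {cdn.n_nodes} diseases, {cdn.n_edges} edges, GEF={stats.fraction:.3f}")
report = gef_significance(cdn, method="er", replicates=999, seed=7, n_swaps=5000)
print(f"edge-randomization p-value: {report.p_value:.4f} ({report.p_bound})")
```

prints

```
precision=0.935 recall=0.479 F=0.634
CDN: 22 diseases, 24 edges, GEF=0.000
edge-randomization p-value: 0.0010 (p < 0.001001)
```

Reading: from 600 noisy synthetic abstracts (30 diseases, 8 planted terms
each, ~2 spurious terms per abstract) the filter recovers disease models
at 93% precision; the unfiltered recognizer output scores F ≈ 0.33 on the
same corpora, against F = 0.63 here. Every edge of the resulting disease
network joins diseases affecting the same organ system (GEF 0), and none
of 999 degree-preserving rewirings achieves so low a fraction, so the
clustering is significant at the resolution of the test (p = 1/1000).

## Command line

The same workflow is available as a thin CLI:

```sh
phenominer synth --out-dir work --seed 7          # toy ontology + corpus + truth
phenominer annotate --obo work/ontology.obo --abstracts work/abstracts.jsonl \
    --whitelist work/whitelist.txt --models-out work/models.tsv
phenominer network --obo work/ontology.obo --models work/models.tsv \
    --categories work/categories.tsv --simcut 1.5 --out work/cdn.tsv
phenominer gef --cdn work/cdn.tsv --replicates 1000 --seed 7
```

Abstracts are read as line-delimited JSON (`id`, `title`, `abstract`,
`mesh`) or 4-column TSV; networks export as edge TSV (lossless), SIF, or
GraphML.

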