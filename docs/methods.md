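# Methods

## Problem

Curated phenotype annotations (disease → ontology term) exist at scale for
rare Mendelian disorders but not for common disease. `phenominer`
implements a literature-mining route to such annotations: abstracts
indexed under disease descriptors are scanned for phenotype-ontology
terms, and the co-occurrence statistics of terms and diseases are filtered
into per-disease term sets ("disease models"). The models are then
validated intrinsically by building a disease similarity network and
testing whether its structure recapitulates an independent categorical
disease classification.

## Concept recognition

Recognition is a normalized dictionary lookup: every term label and
synonym is indexed under a canonical form (lowercased, punctuation folded
to spaces, whitespace collapsed), and text is scanned with a greedy
longest-match, left-to-right, non-overlapping window of at most 7 tokens
(enough for the label lengths seen in phenotype ontologies; configurable).
Titles and bodies are both scanned. There is deliberately no stemming (off
by default) and no negation detection: the downstream
frequency/specificity filter absorbs recognition noise, so the recognizer
is kept simple and conservative. Conjunction decomposition and
non-canonical phrase alignment ("fingers are short and broad") are out of
scope; on real text this recognizer under-counts relative to a full
phenotype NLP system, which lowers recall of rare surface forms but does
not change the statistical machinery downstream.

## Term weighting

With diseases in the role of documents, for term *t* and disease *D*:

- TF(t, D): number of D-indexed abstracts in which *t* appears at least
  once. Multiple mentions within one abstract count once.
- IDF(t, D) = log(T_D / |{d : t mentioned in ≥1 abstract of d}|), with
  T_D the number of diseases in the corpus.
- TFIDF = TF × IDF; TFIDFIC = TFIDF × IC(t).
- IC(t) = −log p(t), where p(t) is the fraction of abstracts annotated
  with *t* or any descendant (ancestor propagation: annotating a term
  implies all its ancestors). Terms never annotated have p = 0; their IC
  is stored as +∞, they are flagged, and they are excluded from MICA
  maximization and contribute TFIDFIC = 0.

Logarithms are natural by default; the base is a configuration option
(any fixed base rescales all scores consistently).

Two IC tables coexist and must not be conflated: the **abstract-level**
table above feeds TFIDFIC, while the **disease-level** table (p = the
proportion of diseases annotated with the term or a descendant) feeds the
semantic similarity used for the disease network.

## The filter

Three thresholds (n, m, e) drive a per-disease procedure:

1. **Seeds.** Terms with TFIDF ≥ n become clustering seeds (ties at the
   threshold are seeds). If no term qualifies, the single best-TFIDF term
   is kept as a flagged one-term model so that every disease retains at
   least one annotation.
2. **Grouping.** Seeds are grouped by their top-level category ancestors —
   the children of the "phenotypic abnormality" sub-root, i.e. the major
   organ systems. A term descending from several categories joins every
   such group; the final model is deduplicated. The premise is that a
   disease affects few organ systems, so true annotations concentrate in
   few groups.
3. **Density reduction.** Each group is reduced to the subset minimizing
   its *density*: the population standard deviation of all pairwise
   shortest-path lengths in the ontology (is-a edges traversed
   undirected). Pairwise distances are integers, so subsets are compared
   by exact rational variance (no float ties). Ties resolve to the larger
   subset, then the smaller mean distance, then the lexicographically
   smallest id tuple — retaining more candidates without losing
   determinism. Groups of ≤ 12 terms are searched exhaustively; larger
   groups use an assignment-seeded heuristic (order terms by mutual
   proximity starting from the tightest assignment pair, then score all
   prefixes of the ordering), with the exhaustive search as the oracle in
   tests.
4. **Extension.** Leftover terms (below n) surviving a TFIDFIC ≥ m prune
   are considered for re-admission: a leftover joins its group's model if
   adding it to the seed subset keeps |density − seed density| ≤ e. Each
   leftover is judged against the seed subset independently rather than
   against a growing working set. This makes the outcome independent of
   processing order and strictly monotone in e (raising the margin never
   drops an accepted term), both of which an incremental variant would
   violate; survivors are still iterated in descending TFIDFIC order for
   deterministic reporting.

Parameters can be learned per disease category by exhaustive grid search
against a gold standard, maximizing micro F-score or precision, with ties
resolved to the smallest n, then m, then e.

Defaults are n = 5, m = 5, e = 1. At the synthetic study conditions below
a planted term appearing in most of a disease's ~20 abstracts has TFIDF
well above 10 while scattered noise terms sit below ~4, so the defaults
sit between the two populations rather than on a boundary; they are
ordinary starting points, and the grid search is the intended route to
tuned values on any real corpus.

## Similarity and the disease network

- **Subsumption-extended Jaccard.** Terms of two sets match when equal or
  related by ancestry at any distance. Matches are counted through a
  maximum bipartite matching (each term consumed once), so the index
  reduces to the classic Jaccard when only exact matches exist and stays
  in [0, 1]. Counting all matching *pairs* instead would exceed 1; the
  matching formulation is the package's resolution of that ambiguity.
- **Symmetric semantic similarity.** Resnik-style: the similarity of two
  terms is the IC of their most informative common ancestor (MICA; ties
  broken by depth, then id). For two diseases, each query term takes its
  best match in the other set, directed scores average over query terms,
  and the two directions are averaged.

The common-disease network (CDN) draws an edge between diseases whose
symmetric similarity strictly exceeds a cutoff (`simcut`, default 2.0);
isolated diseases are dropped. Nodes carry one or more disease-category
labels, and an edge is *gray* when its endpoints share no category (a
node pair sharing any one of several categories is not gray). The
gray-edge fraction (GEF) — gray edges over all edges — measures agreement
between phenotypic clustering and the categorical classification.

## Randomization tests

- **Edge randomization (er)**: repeated attempted swaps A-B, X-Y → A-Y,
  X-B, skipping attempts that would create an existing edge or self-loop
  (skips count toward the attempt budget). Degrees are preserved exactly;
  10,000 attempts is the default chain length.
- **Annotation randomization (ar)**: a fraction (default 50%) of each
  disease's terms is replaced by uniform draws from the abnormality
  subtree, excluding the disease's own original terms and avoiding
  duplicates; the entire similarity matrix and network are rebuilt per
  replicate, so node and edge counts may change. Replicates whose rebuilt
  network has no edges are excluded from the null and reported as
  degenerate. The replicate `simcut` defaults to the observed one and can
  be lowered (the characteristic choice is 1.4 versus an observed 2.0)
  to keep replicate networks comparable in size.

Empirical significance uses the add-one convention
p = (1 + #{null ≤ observed}) / (1 + replicates), which can never be
exactly zero; when no null reaches the observed GEF the conventional
strict bound ("p < 1/replicates") is reported alongside.

## Synthetic data

The generator emulates the statistical structure the filter assumes.
A toy ontology (default: root, an abnormality sub-root, 8 top-level
category terms, a random ~24-term tree under each with occasional
diamonds) provides the lexicon; labels are unique coined tokens with one
synonym each, so recognition on synthetic text is exact and recovery
failures are attributable to the statistics, not the lexicon. Each
disease plants a term set (default 8 terms) drawn from the leaves of one
or two top-level categories; each of its abstracts (default 20) mentions
every planted term independently with probability 0.8 (via the synonym
30% of the time) plus Poisson(noise_rate) off-plant leaf terms; filler
text is generic methods vocabulary that cannot collide with the lexicon.
Defaults — 30 diseases, 8 terms, 20 abstracts, mention probability 0.8,
noise rate 2.0 — are the package's standing synthetic study conditions: a
modest corpus where planted terms are frequent-but-imperfect and noise
is substantial (noise mentions outnumber any single planted term's
mentions in expectation).

What the generator does **not** emulate: ambiguous or overlapping surface
forms, negated mentions, abstracts indexed under multiple diseases,
correlated noise (e.g. comorbidity vocabulary), and realistic label
lengths. Passing recovery tests therefore demonstrate that the filter
separates frequent-and-concentrated signal from scattered noise, not that
any particular precision is attainable on PubMed-scale text.

## Validation experiments

`phenominer.experiments` packages three end-to-end studies, all runnable
from `scripts/acceptance.py`:

- **Recovery**: over 20 synthetic corpora at the study conditions above,
  the mean micro F-score of filtered models against the planted truth is
  compared with the unfiltered recognizer output and with a size-matched
  uniform random selection from each disease's raw terms.
- **Modular-network significance**: a two-block planted network (two
  20-node categories, 50 within-block edges each, no cross edges) has
  GEF 0; with 500 er replicates no null reaches it, so the p-value is
  exactly 1/501.
- **p-value calibration**: with an observed network drawn from the
  rewiring null itself (a 60-node, 300-edge random graph with two random
  categories, rewired with 2,400 attempts), p-values over 400 trials at
  149 replicates each are compared with the uniform distribution by the
  Kolmogorov–Smirnov distance. The chain length of 8 attempts per edge
  matters here: short chains leave the null correlated with the observed
  draw and visibly inflate the p-values. The discrete GEF and the add-one
  rule leave a small conservative bias, so the KS distance is expected in
  the 0.03–0.09 range rather than at the pure-sampling floor.

Problem sizes throughout (corpus sizes, replicate counts, network sizes)
are chosen so each experiment completes in seconds to a couple of minutes
on one CPU; all scale linearly if larger runs are wanted.

## Numerical and degenerate-input choices

- Subset comparison in the density search uses exact `Fraction`
  arithmetic; reported densities are floats.
- Precision/recall with zero denominators are reported as 0 with an
  explicit `*_defined = False` flag; F is 0 when both components are 0.
- Empty annotation sets are rejected by the symmetric similarity (the
  pipeline excludes empty models before network construction).
- Diseases whose whitelist descriptor matches no abstract are dropped
  from the corpus (with a warning) rather than kept as empty documents.
- `mica` requires a common ancestor with defined IC and raises otherwise;
  the pairwise-similarity scorer instead scores an unannotated meet as 0
  (a vacuous root-level match).

## Known limitations

- The dictionary recognizer has no stemming, inflection handling, or
  negation awareness; on real abstracts it trades recall for precision.
- The assignment-based heuristic for density reduction on groups larger
  than 12 terms is not guaranteed optimal; it is bounded by the full
  group's density and oracle-tested only at exhaustive sizes.
- Whether leftover terms may form clusters in categories containing no
  seed subset is ambiguous in the underlying procedure; here they cannot
  (they are dropped), which biases models toward seeded organ systems.
- The ar test's replicate networks can collapse at high cutoffs; the
  degenerate-replicate count should be inspected before trusting its p.
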