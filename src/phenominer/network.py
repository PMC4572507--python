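"""The common-disease network (CDN) and its randomization tests.

Diseases are nodes; an edge joins two diseases whose symmetric semantic
similarity strictly exceeds a cutoff (simcut).  Each node carries the set
of disease categories it belongs to.  An edge is *gray* when its
endpoints share no category, and the gray-edge fraction (GEF) — the
proportion of gray edges — measures how well phenotypic clustering agrees
with the categorical classification (lower = better agreement).

Significance of an observed GEF is assessed empirically against two null
models: degree-preserving edge rewiring (er), and annotation randomization
(ar), where a fraction of each disease's terms is replaced by random
ontology terms and the whole network is rebuilt.  Empirical p-values use
the add-one convention p = (1 + #{null <= observed}) / (1 + replicates),
never exactly zero; when no null reaches the observed value the
conventional strict bound (e.g. "p < 0.001") is reported alongside.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np

from .ontology import ICTable, Ontology, TermId
from .similarity import AnnotationSet, SimilarityMatrix, pairwise_similarity

__all__ = [
    "CDN",
    "GrayEdgeStats",
    "GEFReport",
    "ARInputs",
    "build_cdn",
    "gray_edge_fraction",
    "edge_randomize",
    "annotation_randomize",
    "gef_significance",
    "export_graph",
    "import_edge_tsv",
]


@dataclass
class CDN:
    """Weighted undirected disease graph with per-node category sets."""

    graph: nx.Graph
    simcut: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def categories(self, node: str) -> frozenset[str]:
        return self.graph.nodes[node]["categories"]

    def degree_sequence(self) -> dict[str, int]:
        return dict(self.graph.degree())


def build_cdn(
    matrix: SimilarityMatrix,
    categories: Mapping[str, Iterable[str]],
    simcut: float,
) -> CDN:
    """Draw an edge for every pair whose similarity strictly exceeds simcut.

    Isolated diseases are excluded from the network.  Every matrix disease
    must appear in the category map (a disease may carry several
    categories).
    """
    if simcut < 0:
        raise ValueError("simcut must be non-negative")
    missing = [d for d in matrix.ids if d not in categories]
    if missing:
        raise KeyError(f"diseases missing from category map: {missing[:5]}")
    graph = nx.Graph()
    ids = matrix.ids
    vals = matrix.values
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            w = float(vals[i, j])
            if w > simcut:
                graph.add_edge(ids[i], ids[j], weight=w)
    for node in graph.nodes:
        graph.nodes[node]["categories"] = frozenset(categories[node])
    return CDN(graph=graph, simcut=simcut)


class GrayEdgeStats(NamedTuple):
    gray_edges: int
    total_edges: int
    fraction: float


def gray_edge_fraction(cdn: CDN) -> GrayEdgeStats:
    """Count edges whose endpoints share no disease category."""
    total = cdn.n_edges
    if total == 0:
        raise ValueError("gray-edge fraction is undefined on an edgeless network")
    gray = sum(
        1
        for u, v in cdn.graph.edges
        if not (cdn.categories(u) & cdn.categories(v))
    )
    return GrayEdgeStats(gray_edges=gray, total_edges=total, fraction=gray / total)


def edge_randomize(
    cdn: CDN,
    n_swaps: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> CDN:
    """Degree-preserving rewiring by random pairwise edge swaps.

    Each of ``n_swaps`` attempts picks two edges A-B and X-Y (randomly
    oriented) and rewires them to A-Y and X-B.  The attempt is skipped —
    still counting toward ``n_swaps`` — when either replacement edge
    already exists or would be a self-loop.  Node degrees and the edge
    count are preserved exactly; weights travel with the surviving
    endpoint pair of the rewired edges and are not meaningful afterwards.
    """
    if cdn.n_edges < 2:
        raise ValueError("edge randomization needs at least two edges")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes, edges = _pack_edges(cdn)
    edge_set = {min(u, v) * len(nodes) + max(u, v) for u, v, _ in edges}
    _swap_loop(edges, edge_set, len(nodes), n_swaps, rng)
    graph = nx.Graph()
    graph.add_nodes_from(cdn.graph.nodes(data=True))
    for u, v, w in edges:
        graph.add_edge(nodes[u], nodes[v], weight=w)
    return CDN(graph=graph, simcut=cdn.simcut)


def _pack_edges(cdn: CDN) -> tuple[list[str], list[tuple[int, int, float]]]:
    nodes = list(cdn.graph.nodes)
    node_id = {u: i for i, u in enumerate(nodes)}
    edges = [
        (node_id[u], node_id[v], d.get("weight", 1.0))
        for u, v, d in cdn.graph.edges(data=True)
    ]
    return nodes, edges


def _swap_loop(
    edges: list[tuple[int, int, float]],
    edge_set: set[int],
    n_nodes: int,
    n_swaps: int,
    rng: np.random.Generator,
) -> None:
    """In-place attempted edge swaps on the packed representation."""
    n_edges = len(edges)
    idx = rng.integers(0, n_edges, size=(n_swaps, 2))
    flips = rng.random(size=(n_swaps, 2)) < 0.5
    idx0, idx1 = idx[:, 0].tolist(), idx[:, 1].tolist()
    flip0, flip1 = flips[:, 0].tolist(), flips[:, 1].tolist()
    for k in range(n_swaps):
        i, j = idx0[k], idx1[k]
        if i == j:
            continue
        a, b, w1 = edges[i]
        x, y, w2 = edges[j]
        if flip0[k]:
            a, b = b, a
        if flip1[k]:
            x, y = y, x
        if a == y or x == b:
            continue  # would create a self-loop
        e1 = a * n_nodes + y if a < y else y * n_nodes + a
        e2 = x * n_nodes + b if x < b else b * n_nodes + x
        if e1 == e2 or e1 in edge_set or e2 in edge_set:
            continue
        edge_set.remove(a * n_nodes + b if a < b else b * n_nodes + a)
        edge_set.remove(x * n_nodes + y if x < y else y * n_nodes + x)
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (a, y, w1)
        edges[j] = (x, b, w2)


def annotation_randomize(
    sets: Sequence[AnnotationSet],
    fraction: float,
    ontology: Ontology,
    seed: int | np.random.Generator = 0,
) -> list[AnnotationSet]:
    """Replace a fraction of each disease's terms with random ontology terms.

    floor(fraction x |terms|) uniformly chosen terms are swapped for
    uniform draws from the abnormality subtree.  Replacements avoid both
    duplicates within the set and the disease's original terms (a
    "replacement" never silently restores what it replaced); the set size
    is preserved.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = sorted(ontology.descendants(ontology.abnormality_root, reflexive=True))
    out: list[AnnotationSet] = []
    for s in sets:
        terms = sorted(s.terms)
        k = math.floor(fraction * len(terms))
        if k == 0:
            out.append(s)
            continue
        drop_idx = set(rng.choice(len(terms), size=k, replace=False).tolist())
        kept = {t for i, t in enumerate(terms) if i not in drop_idx}
        original = set(terms)
        candidates = [t for t in pool if t not in original]
        if len(candidates) < k:
            raise ValueError(
                f"abnormality subtree too small to replace {k} terms of {s.owner}"
            )
        new_terms = set(kept)
        while len(new_terms) < len(terms):
            new_terms.add(candidates[int(rng.integers(len(candidates)))])
        out.append(AnnotationSet(owner=s.owner, terms=frozenset(new_terms)))
    return out


@dataclass(frozen=True)
class ARInputs:
    """Everything needed to rebuild the CDN per annotation-randomized replicate."""

    sets: tuple[AnnotationSet, ...]
    ic_table: ICTable
    ontology: Ontology
    categories: Mapping[str, Iterable[str]]
    fraction: float = 0.5
    simcut: float | None = None  # None = observed network's simcut


@dataclass
class GEFReport:
    """Observed GEF, its null distribution, and the empirical p-value."""

    observed_gef: float
    gray_edges: int
    total_edges: int
    null_values: list[float]
    p_value: float
    method: str
    replicates: int
    seed: int | None = None
    p_bound: str | None = None
    n_degenerate: int = 0  # ar replicates whose rebuilt network had no edges

    def to_json(self, path_or_buf=None) -> str:
        payload = {
            "observed_gef": self.observed_gef,
            "gray_edges": self.gray_edges,
            "total_edges": self.total_edges,
            "p_value": self.p_value,
            "p_bound": self.p_bound,
            "method": self.method,
            "replicates": self.replicates,
            "seed": self.seed,
            "n_degenerate": self.n_degenerate,
            "null_values": self.null_values,
        }
        text = json.dumps(payload, indent=1)
        if path_or_buf is not None:
            if hasattr(path_or_buf, "write"):
                path_or_buf.write(text)
            else:
                with open(path_or_buf, "w") as fh:
                    fh.write(text)
        return text


def gef_significance(
    cdn: CDN,
    method: str = "er",
    replicates: int = 1000,
    seed: int = 0,
    n_swaps: int = 10_000,
    ar_inputs: ARInputs | None = None,
) -> GEFReport:
    """Empirical significance of the observed gray-edge fraction.

    "er" rewires the observed network's edges (degree-preserving); "ar"
    re-randomizes annotations and rebuilds the network per replicate,
    which may change its node and edge counts — edgeless replicates are
    excluded from the null and counted as degenerate.  The p-value is the
    add-one fraction of null GEFs at or below the observed one.
    """
    observed = gray_edge_fraction(cdn)
    rng = np.random.default_rng(seed)
    nulls: list[float] = []
    n_degenerate = 0
    if method == "er":
        # run the swap chains on the packed representation; only the gray
        # count is needed per replicate, not a rebuilt graph
        nodes, base_edges = _pack_edges(cdn)
        cats = [cdn.graph.nodes[u]["categories"] for u in nodes]
        base_set = {min(u, v) * len(nodes) + max(u, v) for u, v, _ in base_edges}
        for _ in range(replicates):
            edges = list(base_edges)
            _swap_loop(edges, set(base_set), len(nodes), n_swaps, rng)
            gray = sum(1 for u, v, _ in edges if not (cats[u] & cats[v]))
            nulls.append(gray / len(edges))
    elif method == "ar":
        if ar_inputs is None:
            raise ValueError("annotation randomization requires ar_inputs")
        simcut = ar_inputs.simcut if ar_inputs.simcut is not None else cdn.simcut
        for _ in range(replicates):
            rnd_sets = annotation_randomize(
                list(ar_inputs.sets), ar_inputs.fraction, ar_inputs.ontology, rng
            )
            matrix = pairwise_similarity(
                ar_inputs.ontology, ar_inputs.ic_table, rnd_sets
            )
            replicate = build_cdn(matrix, ar_inputs.categories, simcut)
            if replicate.n_edges == 0:
                n_degenerate += 1
                continue
            nulls.append(gray_edge_fraction(replicate).fraction)
    else:
        raise ValueError(f"unknown method {method!r}")

    n_valid = len(nulls)
    count = sum(1 for v in nulls if v <= observed.fraction)
    p_value = (1 + count) / (1 + n_valid) if n_valid else 1.0
    p_bound = None
    if n_valid and count == 0:
        p_bound = f"p < {1.0 / n_valid:.6g}"
    return GEFReport(
        observed_gef=observed.fraction,
        gray_edges=observed.gray_edges,
        total_edges=observed.total_edges,
        null_values=nulls,
        p_value=p_value,
        method=method,
        replicates=replicates,
        seed=seed,
        p_bound=p_bound,
        n_degenerate=n_degenerate,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_graph(cdn: CDN, fmt: str = "edge-tsv") -> str:
    """Serialize a CDN as edge TSV (lossless), SIF, or GraphML."""
    if fmt == "edge-tsv":
        lines = [f"#simcut\t{cdn.simcut!r}"]
        lines.append(
            "disease_a\tdisease_b\tweight\tis_gray\tcategories_a\tcategories_b"
        )
        for u, v, d in sorted(cdn.graph.edges(data=True)):
            gray = int(not (cdn.categories(u) & cdn.categories(v)))
            lines.append(
                "\t".join(
                    [
                        u,
                        v,
                        repr(float(d.get("weight", 1.0))),
                        str(gray),
                        "|".join(sorted(cdn.categories(u))),
                        "|".join(sorted(cdn.categories(v))),
                    ]
                )
            )
        return "\n".join(lines) + "\n"
    if fmt == "sif":
        return "".join(
            f"{u}\tsim\t{v}\n" for u, v in sorted(cdn.graph.edges)
        )
    if fmt == "graphml":
        g = nx.Graph()
        for node, data in cdn.graph.nodes(data=True):
            g.add_node(node, categories="|".join(sorted(data["categories"])))
        for u, v, d in cdn.graph.edges(data=True):
            g.add_edge(u, v, weight=float(d.get("weight", 1.0)))
        buf = io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue().decode()
    raise ValueError(f"unknown export format {fmt!r}")


def import_edge_tsv(text: str) -> CDN:
    """Inverse of ``export_graph(..., "edge-tsv")``."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#simcut\t"):
        raise ValueError("missing #simcut header")
    simcut = float(lines[0].split("\t", 1)[1])
    graph = nx.Graph()
    for ln in lines[2:]:
        u, v, w, _gray, cats_a, cats_b = ln.split("\t")
        graph.add_edge(u, v, weight=float(w))
        graph.nodes[u]["categories"] = frozenset(c for c in cats_a.split("|") if c)
        graph.nodes[v]["categories"] = frozenset(c for c in cats_b.split("|") if c)
    return CDN(graph=graph, simcut=simcut)
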