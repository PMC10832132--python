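"""Gene Ontology DAG handling.

Parses OBO (via obonet), keeps only ``is_a`` edges, assigns hierarchy
levels (namespace roots at LEVEL 1, children of roots at LEVEL 2, a
multi-parent term taking its minimum depth), propagates annotations under
the true-path rule, selects label families by protein count, and
classifies levels as head or tail by the average number of proteins (ANP)
per family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet

from .io_formats import AnnotationTable

logger = logging.getLogger("protofun")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class OntologyError(ValueError):
    pass


@dataclass
class GeneOntologyGraph:
    """GO terms with child->parent ``is_a`` edges, roots and levels."""

    graph: nx.DiGraph  # edges child -> parent
    roots: dict[str, str]  # namespace -> root term id
    levels: dict[str, int] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def namespace_of(self, term: str) -> str:
        return self.graph.nodes[term]["namespace"]

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable via is_a (excluding the term itself)."""
        return nx.descendants(self.graph, term)

    def descendant_terms(self, term: str) -> set[str]:
        return nx.ancestors(self.graph, term)

    def is_root(self, term: str) -> bool:
        return term in self.roots.values()


def from_edges(
    term_namespaces: dict[str, str], edges: list[tuple[str, str]]
) -> GeneOntologyGraph:
    """Build a graph from explicit (child, parent) pairs; used by fixtures."""
    g = nx.DiGraph()
    for t, ns in term_namespaces.items():
        g.add_node(t, namespace=ns, name=t)
    g.add_edges_from(edges)
    return _finalize(g)


def _finalize(g: nx.DiGraph) -> GeneOntologyGraph:
    if not nx.is_directed_acyclic_graph(g):
        cycle = next(iter(nx.simple_cycles(g)))
        raise OntologyError(f"ontology contains a cycle through {cycle[0]!r}")
    roots: dict[str, str] = {}
    for node in g.nodes:
        if g.out_degree(node) == 0:  # no parents
            ns = g.nodes[node]["namespace"]
            if ns in roots:
                raise OntologyError(f"namespace {ns} has multiple roots")
            roots[ns] = node
    ont = GeneOntologyGraph(graph=g, roots=roots)
    assign_levels(ont)
    return ont


def parse_obo(path) -> GeneOntologyGraph:
    """Read an OBO 1.2 file keeping only non-obsolete terms and is_a edges."""
    multi = obonet.read_obo(path, ignore_obsolete=False)
    g = nx.DiGraph()
    n_obsolete = 0
    for node, data in multi.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            n_obsolete += 1
            continue
        g.add_node(
            node,
            namespace=data.get("namespace", "unknown"),
            name=data.get("name", node),
        )
    if n_obsolete:
        logger.info("dropped %d obsolete term(s)", n_obsolete)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a" and child in g and parent in g:
            g.add_edge(child, parent)
    if not g.nodes:
        raise OntologyError(f"no usable terms in {path}")
    return _finalize(g)


def assign_levels(ont: GeneOntologyGraph) -> GeneOntologyGraph:
    """Level = 1 + shortest is_a path to the namespace root (root = 1)."""
    levels: dict[str, int] = {}
    rev = ont.graph.reverse(copy=False)  # parent -> child
    for ns, root in ont.roots.items():
        for term, depth in nx.single_source_shortest_path_length(rev, root).items():
            lvl = depth + 1
            if term not in levels or lvl < levels[term]:
                levels[term] = lvl
    unreachable = ont.terms - set(levels)
    if unreachable:
        raise OntologyError(
            f"term(s) not reachable from any root: {sorted(unreachable)[:5]}"
        )
    ont.levels = levels
    return ont


def propagate_annotations(
    table: AnnotationTable, ont: GeneOntologyGraph
) -> AnnotationTable:
    """True-path closure: (p, t) implies (p, a) for every non-root ancestor.

    Idempotent; root terms are excluded from the propagated set.
    """
    roots = set(ont.roots.values())
    anc_cache: dict[str, set[str]] = {}
    pairs: set[tuple[str, str]] = set()
    for pid, term in table.pairs:
        if term in roots:
            continue
        pairs.add((pid, term))
        if term not in anc_cache:
            anc_cache[term] = ont.ancestors(term) - roots
        pairs.update((pid, a) for a in anc_cache[term])
    return AnnotationTable(pairs=pairs, propagated=True)


@dataclass
class LabelSpace:
    """Ordered selected GO terms with counts, levels and head/tail flags."""

    terms: list[str]
    counts: dict[str, int]
    levels: dict[str, int]
    head_levels: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.terms)

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}


def term_counts(table: AnnotationTable) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, term in table.pairs:
        counts[term] = counts.get(term, 0) + 1
    return counts


def select_label_families(
    table: AnnotationTable, ont: GeneOntologyGraph, min_count: int = 50
) -> LabelSpace:
    """Keep terms annotated to strictly more than *min_count* proteins.

    Roots are excluded.  Ordering is deterministic: by level, then term id.
    """
    if not table.propagated:
        raise OntologyError("label selection requires a propagated table")
    counts = term_counts(table)
    roots = set(ont.roots.values())
    kept = [t for t, c in counts.items() if c > min_count and t not in roots]
    if not kept:
        raise OntologyError(
            f"no family has more than {min_count} proteins; "
            "lower the threshold for small cohorts"
        )
    kept.sort(key=lambda t: (ont.levels[t], t))
    return LabelSpace(
        terms=kept,
        counts={t: counts[t] for t in kept},
        levels={t: ont.levels[t] for t in kept},
    )


def anp_per_level(
    table: AnnotationTable, ont: GeneOntologyGraph, terms: list[str] | None = None
) -> dict[int, float]:
    """Average number of proteins (ANP) per family, by hierarchy level."""
    if not table.propagated:
        raise OntologyError("ANP requires a propagated table")
    counts = term_counts(table)
    if terms is not None:
        counts = {t: c for t, c in counts.items() if t in set(terms)}
    by_level: dict[int, list[int]] = {}
    for t, c in counts.items():
        by_level.setdefault(ont.levels[t], []).append(c)
    return {lvl: sum(cs) / len(cs) for lvl, cs in sorted(by_level.items())}


def classify_head_tail(
    anp: dict[int, float], cutoff: float = 2000.0
) -> dict[int, str]:
    """Head iff the level's ANP >= cutoff (boundary inclusive), else tail."""
    return {lvl: ("head" if v >= cutoff else "tail") for lvl, v in anp.items()}
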