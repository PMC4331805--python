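"""Gene Ontology DAG, gene annotations, and flat pathway collections.

GO terms form a directed acyclic graph; an annotation attached to a
term is inherited by every ancestor of that term (the true-path rule),
so a term's effective gene set is the union of the direct annotations
of the term itself and of all its descendants.  Propagation follows
the ``is_a`` and ``part_of`` relations only — the pair for which
ancestor inheritance is semantically safe; other relationship types
are dropped with a logged count.

Pathways are flat (database_label, pathway_name) -> gene-set entries
read from GMT, where the description column carries the source
database label.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import obonet
from Bio.UniProt import GOA

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "AnnotationSet",
    "PathwayCollection",
    "parse_obo",
    "parse_gaf",
    "propagate",
    "parse_gmt",
    "annotated_genes",
]

#: child->parent relations along which annotations are inherited.
PROPAGATING_RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class OntologyDAG:
    """GO terms with typed child->parent edges.

    ``graph`` is a DiGraph whose edges point child -> parent and carry
    a ``relation`` attribute in :data:`PROPAGATING_RELATIONS`; it is
    acyclic by construction.  Obsolete terms are recorded separately,
    carry no edges and receive no annotations.
    """

    terms: Mapping[str, tuple[str, str]]  # term_id -> (name, namespace)
    graph: nx.DiGraph
    obsolete: frozenset[str] = frozenset()

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id][1]

    def parents(self, term_id: str) -> set[str]:
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        return set(self.graph.predecessors(term_id))

    def descendants(self, term_id: str) -> set[str]:
        """All terms below ``term_id`` (excluding itself)."""
        return set(nx.ancestors(self.graph, term_id))


@dataclass
class AnnotationSet:
    """Direct and propagated gene memberships per GO term."""

    direct: dict[str, frozenset[str]] = field(default_factory=dict)
    propagated: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.direct.values():
            out |= genes
        return out

    def genes(self, term_id: str) -> frozenset[str]:
        """Propagated gene set of a term (empty if unknown)."""
        return self.propagated.get(term_id, frozenset())


@dataclass(frozen=True)
class PathwayCollection:
    """Flat (database_label, pathway_name) -> gene-set entries."""

    pathways: Mapping[tuple[str, str], frozenset[str]]

    def __post_init__(self) -> None:
        for key, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {key} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def genes(self, key: tuple[str, str]) -> frozenset[str]:
        return self.pathways.get(key, frozenset())


def parse_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2 ontology into an :class:`OntologyDAG`.

    ``is_a`` and ``relationship: part_of`` edges are retained; other
    relationship types are dropped with a logged count.  A cycle among
    the retained edges or an edge to an undeclared term is a hard
    error.
    """
    multigraph = obonet.read_obo(path, ignore_obsolete=False)
    terms: dict[str, tuple[str, str]] = {}
    obsolete: set[str] = set()
    for term_id, data in multigraph.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            obsolete.add(term_id)
            continue
        if "name" not in data and "namespace" not in data:
            # obonet materialises undeclared edge targets as bare nodes
            continue
        terms[term_id] = (data.get("name", term_id), data.get("namespace", ""))

    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    dropped = 0
    for child, parent, relation in multigraph.edges(keys=True):
        if child in obsolete or parent in obsolete:
            continue
        if relation not in PROPAGATING_RELATIONS:
            dropped += 1
            continue
        if parent not in terms:
            raise ValueError(
                f"{path}: edge {child} -{relation}-> {parent} targets an "
                "undeclared term"
            )
        graph.add_edge(child, parent, relation=relation)
    if dropped:
        logger.info("parse_obo: dropped %d non-propagating edge(s)", dropped)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"{path}: ontology contains a cycle: {cycle}")
    return OntologyDAG(terms=terms, graph=graph, obsolete=frozenset(obsolete))


def parse_gaf(path: str | Path, dag: OntologyDAG) -> AnnotationSet:
    """Read GAF 2.x gene->GO annotations (direct only; propagation separate).

    Rows with a NOT qualifier are skipped, as are rows citing terms
    that are obsolete or absent from the DAG (counted and logged).
    Duplicate (gene, term) rows collapse.  Zero usable rows is a hard
    error.
    """
    # Pre-screen lines so one malformed row is a warning, not a crash,
    # and so files without a !gaf-version header still parse.
    good_lines: list[str] = []
    malformed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("!") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) < 15:
                logger.warning("%s:%d: malformed GAF line, skipped", path, lineno)
                malformed += 1
                continue
            good_lines.append(line)
    if malformed:
        logger.warning("parse_gaf: skipped %d malformed line(s)", malformed)

    direct: dict[str, set[str]] = {}
    skipped_not = skipped_unknown = 0
    handle = io.StringIO("!gaf-version: 2.1\n" + "".join(good_lines))
    for rec in GOA.gafiterator(handle):
        gene = rec.get("DB_Object_ID") or rec.get("DB_Object_Symbol")
        term = rec.get("GO_ID")
        if not gene or not term:
            continue
        qualifiers = rec.get("Qualifier") or []
        if any("NOT" in str(q).split("|") or q == "NOT" for q in qualifiers):
            skipped_not += 1
            continue
        if term not in dag or term in dag.obsolete:
            skipped_unknown += 1
            continue
        direct.setdefault(term, set()).add(gene)
    if skipped_not:
        logger.info("parse_gaf: skipped %d NOT-qualified row(s)", skipped_not)
    if skipped_unknown:
        logger.warning(
            "parse_gaf: skipped %d row(s) citing obsolete/unknown terms",
            skipped_unknown,
        )
    if not direct:
        raise ValueError(f"{path}: no usable annotation rows")
    return AnnotationSet(
        direct={t: frozenset(g) for t, g in direct.items()}, propagated={}
    )


def propagate(dag: OntologyDAG, ann: AnnotationSet) -> AnnotationSet:
    """Fill propagated memberships: each term inherits its descendants' genes.

    ``propagated[t]`` is the union of direct annotations over t and
    every term below it, following ``is_a``/``part_of`` child->parent.
    Idempotent and free of hidden state; terms with no genes anywhere
    below them get an empty set.
    """
    propagated: dict[str, set[str]] = {
        t: set(ann.direct.get(t, ())) for t in dag.terms
    }
    # children before parents: topological order of the child->parent graph
    for term in nx.topological_sort(dag.graph):
        genes = propagated[term]
        for parent in dag.graph.successors(term):
            propagated[parent] |= genes
    return AnnotationSet(
        direct=dict(ann.direct),
        propagated={t: frozenset(g) for t, g in propagated.items()},
    )


def parse_gmt(path: str | Path) -> PathwayCollection:
    """Read GMT gene sets: ``name TAB description TAB gene1 TAB gene2 ...``.

    The description field is used as the source-database label (empty
    description -> label ``""``).  Lines with no genes are skipped with
    a warning; the same (database, name) appearing twice with a
    different gene set is a hard error.
    """
    pathways: dict[tuple[str, str], frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
                logger.warning(
                    "%s:%d: gene set %r has no genes, skipped",
                    path, lineno, parts[0],
                )
                continue
            name, database = parts[0], parts[1]
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            key = (database, name)
            if key in pathways and pathways[key] != genes:
                raise ValueError(
                    f"{path}:{lineno}: duplicate pathway {key} with a "
                    "different gene set"
                )
            pathways[key] = genes
    return PathwayCollection(pathways)


def annotated_genes(
    source: AnnotationSet | PathwayCollection,
    term,
    universe_filter: set[str] | frozenset[str],
) -> frozenset[str]:
    """A term's gene set restricted to the analysis universe.

    For GO the propagated set is used; for pathways the flat set.  The
    intersection with ``universe_filter`` keeps the annotated count M
    on the same footing as the universe size N of the enrichment test.
    """
    if isinstance(source, AnnotationSet):
        genes = source.genes(term)
        if term not in source.propagated:
            logger.warning("annotated_genes: unknown GO term %r", term)
    else:
        genes = source.genes(term)
        if term not in source.pathways:
            logger.warning("annotated_genes: unknown pathway %r", term)
    return frozenset(genes & universe_filter)
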