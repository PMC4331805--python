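"""Functional annotation of lncRNA sets.

A set of lncRNAs (for example a co-expressed cluster, or the lncRNAs
differential between two conditions) is annotated through the union
of protein-coding genes co-expressed with its members.  To keep the
union from being dominated by genes touching only one member of a
large set, a support threshold K keeps only coding genes co-expressed
with at least K of the query lncRNAs; K defaults to 1, the plain
union.  Support counts never weight the enrichment test — the query
is the plain set of supported genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .coexpression import CoexpressionNetwork
from .enrichment import AnnotationOutcome, FunctionalAnnotator, enrich

logger = logging.getLogger(__name__)

__all__ = ["SetQuery", "SetAnnotationOutcome", "supported_gene_union", "annotate_set"]


@dataclass(frozen=True)
class SetQuery:
    """A query set of lncRNA ids with a minimum support count K >= 1."""

    lncrna_ids: frozenset[str]
    k: int = 1

    def __post_init__(self) -> None:
        if not self.lncrna_ids:
            raise ValueError("empty lncRNA query set")
        if self.k < 1:
            raise ValueError(f"K must be >= 1, got {self.k}")

    @classmethod
    def from_ids(cls, ids: Iterable[str], k: int = 1) -> "SetQuery":
        return cls(lncrna_ids=frozenset(ids), k=k)


@dataclass(frozen=True)
class SetAnnotationOutcome(AnnotationOutcome):
    """Set-level outcome; additionally reports per-gene support counts and
    the query lncRNAs that were absent from the network."""

    support: dict[str, int] = field(default_factory=dict)
    skipped_lncrnas: tuple[str, ...] = ()


def supported_gene_union(
    network: CoexpressionNetwork, query: SetQuery
) -> tuple[set[str], dict[str, int], list[str]]:
    """Coding genes co-expressed with >= K query lncRNAs.

    Returns ``(genes, support, skipped)`` where ``support`` maps every
    coding gene touched by any query member to the number of members
    it is co-expressed with, and ``skipped`` lists query lncRNAs
    absent from the network (reported, not silently dropped).  A K
    that eliminates every gene yields an empty set, not an error.
    """
    support: dict[str, int] = {}
    skipped: list[str] = []
    for lnc in sorted(query.lncrna_ids):
        if lnc not in network.lncrna_ids:
            skipped.append(lnc)
            continue
        for gene in network.coexpressed_set(lnc):
            support[gene] = support.get(gene, 0) + 1
    if skipped:
        logger.warning(
            "supported_gene_union: %d query lncRNA(s) absent from the "
            "network: %s", len(skipped), ", ".join(skipped),
        )
    genes = {g for g, c in support.items() if c >= query.k}
    return genes, support, skipped


def annotate_set(
    query: SetQuery,
    annotator: FunctionalAnnotator,
) -> SetAnnotationOutcome:
    """Annotate a set of lncRNAs via its K-supported coding-gene union.

    Runs the same statistical pipeline as single-lncRNA annotation
    with n = |supported union| (GO corrected with BY, pathways with
    BH); the same >= ``min_coexp`` query-size filter applies, so a
    union smaller than that yields a not-annotatable outcome.
    """
    if not hasattr(annotator, "network_"):
        raise RuntimeError("annotator is not fitted")
    label = "+".join(sorted(query.lncrna_ids))
    genes, support, skipped = supported_gene_union(annotator.network_, query)
    if len(skipped) == len(query.lncrna_ids):
        return SetAnnotationOutcome(
            query=label, annotatable=False,
            reason="no query lncRNA is present in the network",
            n_coexpressed=0, support=support, skipped_lncrnas=tuple(skipped),
        )
    if len(genes) < annotator.min_coexp:
        return SetAnnotationOutcome(
            query=label, annotatable=False,
            reason=(
                f"supported union has {len(genes)} gene(s) at K={query.k}; "
                f"minimum is {annotator.min_coexp}"
            ),
            n_coexpressed=len(genes), support=support,
            skipped_lncrnas=tuple(skipped),
        )
    go_results = enrich(
        genes, annotator.go_, annotator.universe_,
        min_term_size=annotator.min_term_size, correction="BY",
        alpha=annotator.alpha, dag=annotator.dag_,
        namespace=annotator.namespace,
    )
    pathway_results = enrich(
        genes, annotator.pathways_, annotator.universe_,
        min_term_size=annotator.min_term_size, correction="BH",
        alpha=annotator.alpha,
    )
    return SetAnnotationOutcome(
        query=label, annotatable=True, reason="",
        n_coexpressed=len(genes),
        go_results=tuple(go_results),
        pathway_results=tuple(pathway_results),
        support=support, skipped_lncrnas=tuple(skipped),
    )
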