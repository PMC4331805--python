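"""Hypergeometric enrichment with size filters and FDR control.

A query gene set (the protein-coding genes co-expressed with one or
more lncRNAs) is tested against every functional term.  With

    N  protein-coding genes in the universe,
    M  of them annotated to term T,
    n  genes in the query,
    m  query genes annotated to T,

the enrichment p-value is the upper hypergeometric tail

    p = sum_{i = m}^{min(n, M)} C(M, i) C(N - M, n - i) / C(N, n),

evaluated in log-space (log-gamma terms combined by log-sum-exp) so
that tails as extreme as 1e-109 carry full relative precision.

Terms annotated to fewer than ``min_term_size`` (default 5) universe
genes are excluded, as are queries smaller than ``min_coexp``
(default 5): the test is unreliable at such sizes and those cases are
reported as "not annotatable" rather than silently empty.

GO p-values are corrected with Benjamini-Yekutieli (the DAG makes the
tests strongly dependent); pathway p-values with Benjamini-Hochberg.
Each call to :func:`enrich` is one correction family: exactly the
terms tested in that call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .coexpression import CoexpressionNetwork
from .ontology import AnnotationSet, OntologyDAG, PathwayCollection, annotated_genes

logger = logging.getLogger(__name__)

__all__ = [
    "TermStats",
    "EnrichmentResult",
    "AnnotationOutcome",
    "FunctionalAnnotator",
    "hypergeom_pvalue",
    "hypergeom_log_pvalue",
    "benjamini_hochberg",
    "benjamini_yekutieli",
    "enrich",
    "annotate_lncrna",
    "results_to_frame",
]


@dataclass(frozen=True)
class TermStats:
    """The (N, M, n, m) contingency of one enrichment test."""

    N: int
    M: int
    n: int
    m: int

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError(f"m >= 0 violated: m={self.m}")
        if self.M > self.N:
            raise ValueError(f"M <= N violated: M={self.M}, N={self.N}")
        if self.n > self.N:
            raise ValueError(f"n <= N violated: n={self.n}, N={self.N}")
        if self.m > min(self.n, self.M):
            raise ValueError(
                f"m <= min(n, M) violated: m={self.m}, n={self.n}, M={self.M}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term with its contingency and raw/corrected p-values."""

    term_id: str
    name: str
    database_label: str
    stats: TermStats
    p_raw: float
    p_corrected: float
    correction_method: str
    significant: bool


@dataclass(frozen=True)
class AnnotationOutcome:
    """Result of annotating one lncRNA (or one lncRNA set).

    ``annotatable`` is False when the query failed the minimum
    co-expressed-gene filter or was absent from the network; ``reason``
    then says why.  This is deliberately distinct from an annotatable
    query that simply has no significant terms.
    """

    query: str
    annotatable: bool
    reason: str
    n_coexpressed: int
    go_results: tuple[EnrichmentResult, ...] = ()
    pathway_results: tuple[EnrichmentResult, ...] = ()


def _log_tail_terms(N: int, M: int, n: int) -> np.ndarray:
    """log pmf of the hypergeometric at i = 0..min(n, M), via log-gamma."""
    upper = min(n, M)
    i = np.arange(0, upper + 1)
    # log C(M, i) + log C(N-M, n-i) - log C(N, n); impossible i have
    # n - i > N - M and are excluded by construction of the support
    lo = max(0, n - (N - M))
    log_pmf = np.full(upper + 1, -np.inf)
    ii = i[i >= lo]
    log_pmf[ii] = (
        gammaln(M + 1) - gammaln(ii + 1) - gammaln(M - ii + 1)
        + gammaln(N - M + 1) - gammaln(n - ii + 1) - gammaln(N - M - n + ii + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return log_pmf


def hypergeom_log_pvalue(stats: TermStats) -> float:
    """Natural log of the upper-tail p-value, exact to ~1e-12 relative.

    Summation runs over the tail i = m..min(n, M) in log-space, so the
    result is meaningful far below the smallest positive float.
    """
    if stats.m == 0:
        return 0.0  # the full support sums to 1 exactly
    log_pmf = _log_tail_terms(stats.N, stats.M, stats.n)
    return float(min(0.0, logsumexp(log_pmf[stats.m:])))


def hypergeom_pvalue(stats: TermStats) -> float:
    """Upper-tail hypergeometric p-value of an (N, M, n, m) contingency.

    Returns exactly 1.0 for m = 0.  Values are accurate in relative
    terms down to the underflow limit of double precision (~1e-308);
    for tails beyond that use :func:`hypergeom_log_pvalue`.
    """
    return math.exp(hypergeom_log_pvalue(stats))


def _tail_pvalues(N: int, M: int, n: int) -> np.ndarray:
    """p-values for every m = 0..min(n, M) at once (shared log-pmf core).

    Index m of the returned array equals
    ``hypergeom_pvalue(TermStats(N, M, n, m))``.
    """
    log_pmf = _log_tail_terms(N, M, n)
    # suffix log-sum-exp, stable cumulative from the largest i down
    rev = log_pmf[::-1]
    out = np.minimum(np.logaddexp.accumulate(rev)[::-1], 0.0)
    out[0] = 0.0
    return np.exp(out)


def _check_unit_interval(pvals: np.ndarray) -> None:
    if pvals.size and (np.min(pvals) < 0 or np.max(pvals) > 1):
        raise ValueError("p-values must lie in [0, 1]")


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, returned in the input order."""
    p = np.asarray(pvals, dtype=float)
    _check_unit_interval(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def benjamini_yekutieli(pvals: Sequence[float]) -> np.ndarray:
    """BY adjusted p-values (BH with the harmonic factor c(m)), input order."""
    p = np.asarray(pvals, dtype=float)
    _check_unit_interval(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


_CORRECTIONS = {"BH": benjamini_hochberg, "BY": benjamini_yekutieli}


def enrich(
    query_genes: Iterable[str],
    terms: AnnotationSet | PathwayCollection,
    universe: Iterable[str],
    min_term_size: int = 5,
    correction: str = "BY",
    alpha: float = 0.05,
    dag: OntologyDAG | None = None,
    namespace: str | None = None,
) -> list[EnrichmentResult]:
    """Test a query gene set against every sufficiently large term.

    Every term with M >= ``min_term_size`` annotated genes (after GO
    propagation and intersection with the universe) is tested; the
    correction family is exactly that set of terms.  All tested terms
    are returned — significant or not — sorted by corrected p
    ascending with ties broken by raw p, then term identifier.

    ``namespace`` (with ``dag``) restricts GO terms to one namespace.
    Query genes outside the universe are dropped with a warning; an
    empty query is a hard error.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(_CORRECTIONS)}")
    query = frozenset(query_genes)
    if not query:
        raise ValueError("empty query gene set")
    outside = query - universe
    if outside:
        logger.warning(
            "enrich: dropped %d query gene(s) outside the universe", len(outside)
        )
        query &= universe
        if not query:
            raise ValueError("no query genes inside the universe")

    is_go = isinstance(terms, AnnotationSet)
    if is_go:
        term_ids: Iterable = terms.propagated.keys()
        if namespace is not None:
            if dag is None:
                raise ValueError("namespace filtering requires the ontology DAG")
            term_ids = [t for t in term_ids if dag.namespace(t) == namespace]
    else:
        term_ids = terms.pathways.keys()

    N, n = len(universe), len(query)
    tested: list[tuple[str, str, str, TermStats, float]] = []
    for term in sorted(term_ids, key=str):
        genes = annotated_genes(terms, term, universe)
        M = len(genes)
        if M < min_term_size:
            continue
        m = len(query & genes)
        p = hypergeom_pvalue(TermStats(N=N, M=M, n=n, m=m))
        if is_go:
            term_id = term
            name = dag.name(term) if dag is not None and term in dag else term
            label = (
                dag.namespace(term) if dag is not None and term in dag else "GO"
            )
        else:
            label, name = term  # (database_label, pathway_name)
            term_id = f"{label}::{name}"
        tested.append((str(term_id), name, label, TermStats(N, M, n, m), p))

    if not tested:
        return []
    p_corr = _CORRECTIONS[correction]([t[4] for t in tested])
    results = [
        EnrichmentResult(
            term_id=tid,
            name=name,
            database_label=label,
            stats=st,
            p_raw=p,
            p_corrected=float(pc),
            correction_method=correction,
            significant=bool(pc < alpha),
        )
        for (tid, name, label, st, p), pc in zip(tested, p_corr)
    ]
    results.sort(key=lambda r: (r.p_corrected, r.p_raw, r.term_id))
    return results


def annotate_lncrna(
    lncrna_id: str,
    network: CoexpressionNetwork,
    go: AnnotationSet,
    pathways: PathwayCollection,
    universe: Iterable[str],
    min_coexp: int = 5,
    min_term_size: int = 5,
    alpha: float = 0.05,
    dag: OntologyDAG | None = None,
    namespace: str | None = None,
) -> AnnotationOutcome:
    """Annotate one lncRNA from its co-expressed coding genes.

    GO terms are corrected with BY and pathways with BH, as two
    separate families.  An lncRNA absent from the network or with
    fewer than ``min_coexp`` co-expressed genes yields an explicit
    not-annotatable outcome.
    """
    if lncrna_id not in network.lncrna_ids:
        return AnnotationOutcome(
            query=lncrna_id, annotatable=False,
            reason="absent from the co-expression network", n_coexpressed=0,
        )
    coexpressed = network.coexpressed_set(lncrna_id)
    if len(coexpressed) < min_coexp:
        return AnnotationOutcome(
            query=lncrna_id, annotatable=False,
            reason=(
                f"only {len(coexpressed)} co-expressed protein-coding gene(s); "
                f"minimum is {min_coexp}"
            ),
            n_coexpressed=len(coexpressed),
        )
    go_results = enrich(
        coexpressed, go, universe, min_term_size=min_term_size,
        correction="BY", alpha=alpha, dag=dag, namespace=namespace,
    )
    pathway_results = enrich(
        coexpressed, pathways, universe, min_term_size=min_term_size,
        correction="BH", alpha=alpha,
    )
    return AnnotationOutcome(
        query=lncrna_id, annotatable=True, reason="",
        n_coexpressed=len(coexpressed),
        go_results=tuple(go_results),
        pathway_results=tuple(pathway_results),
    )


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results: term, database, M/N, m/n, raw and corrected p."""
    rows = [
        {
            "term": r.name,
            "database": r.database_label,
            "background_frequency": f"{r.stats.M}/{r.stats.N}",
            "sample_frequency": f"{r.stats.m}/{r.stats.n}",
            "p_value": r.p_raw,
            "corrected_p_value": r.p_corrected,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "term", "database", "background_frequency", "sample_frequency",
            "p_value", "corrected_p_value", "significant",
        ],
    )


class FunctionalAnnotator(BaseEstimator):
    """Estimator assigning GO terms and pathways to lncRNAs.

    Configure thresholds at construction, bind the reference data with
    :meth:`fit`, then call :meth:`annotate` per lncRNA (or
    ``lncgba.set_analysis.annotate_set`` for lncRNA sets, which reuses
    a fitted annotator).

    Parameters
    ----------
    min_coexp:
        Minimum co-expressed coding genes for a query to be testable.
    min_term_size:
        Minimum universe genes annotated to a term for it to be tested.
    alpha:
        Corrected-p significance cutoff.
    namespace:
        Optional GO namespace restriction (e.g. ``biological_process``).

    Attributes
    ----------
    network_ : CoexpressionNetwork
    go_ : AnnotationSet (propagated)
    pathways_ : PathwayCollection
    universe_ : frozenset of protein-coding gene ids (its size is N)
    """

    def __init__(
        self,
        min_coexp: int = 5,
        min_term_size: int = 5,
        alpha: float = 0.05,
        namespace: str | None = None,
    ) -> None:
        self.min_coexp = min_coexp
        self.min_term_size = min_term_size
        self.alpha = alpha
        self.namespace = namespace

    def fit(
        self,
        network: CoexpressionNetwork,
        go: AnnotationSet,
        pathways: PathwayCollection,
        universe: Iterable[str],
        dag: OntologyDAG | None = None,
    ) -> "FunctionalAnnotator":
        if self.min_coexp < 1 or self.min_term_size < 1:
            raise ValueError("size filters must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not go.propagated:
            raise ValueError(
                "annotation set is not propagated; run ontology.propagate first"
            )
        self.network_ = network
        self.go_ = go
        self.pathways_ = pathways
        self.universe_ = frozenset(universe)
        self.dag_ = dag
        return self

    def annotate(self, lncrna_id: str) -> AnnotationOutcome:
        if not hasattr(self, "network_"):
            raise RuntimeError("annotator is not fitted")
        return annotate_lncrna(
            lncrna_id,
            self.network_,
            self.go_,
            self.pathways_,
            self.universe_,
            min_coexp=self.min_coexp,
            min_term_size=self.min_term_size,
            alpha=self.alpha,
            dag=self.dag_,
            namespace=self.namespace,
        )
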