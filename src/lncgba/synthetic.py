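"""Self-contained synthetic fixtures with known ground truth.

The generator emulates the structure of a multi-tissue expression
panel: a 19-condition matrix containing planted co-expression modules,
each module tying a few lncRNAs to a block of protein-coding genes,
plus unstructured background genes.  Each module's coding genes are
directly annotated to a module-specific leaf GO term (all leaves
hang off a common root) and to a module-specific pathway, so an
end-to-end run has an unambiguous right answer: each planted lncRNA
should recover its module's term.

Correlation is planted with a Gaussian latent factor.  A module gene
is ``s * z + sigma * eps`` where z is the module's latent profile over
conditions and eps is i.i.d. noise; the population correlation between
two module genes is then rho = s**2 / (s**2 + sigma**2), so s is
chosen from the target rho in closed form.  ``rho=None`` generates
independent genes (a null fixture).  Expression values are made
non-negative by a per-matrix shift (correlation is
translation-invariant) or, optionally, by exponentiation.

Everything is reproducible from the config seed; there is no implicit
global random state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, GeneCatalog
from .ontology import AnnotationSet, OntologyDAG, PathwayCollection, propagate

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureConfig",
    "ModuleTruth",
    "FixtureTruth",
    "FixtureBundle",
    "generate_fixture",
    "write_fixture",
    "sample_null_pvalues",
]

ROOT_TERM = "GO:0000000"


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the planted-module generative model.

    Defaults mirror the study conditions the toolkit is aimed at: a
    19-tissue panel, five modules of 20 coding + 3 lncRNA genes with
    within-module correlation 0.95, and 200 unstructured background
    genes (150 coding, 50 lncRNA).
    """

    seed: int
    n_conditions: int = 19
    n_modules: int = 5
    coding_per_module: int = 20
    lnc_per_module: int = 3
    n_background_coding: int = 150
    n_background_lnc: int = 50
    rho: float | None = 0.95
    noise_sd: float = 1.0
    nonneg: str = "shift"  # "shift" or "exp"

    def __post_init__(self) -> None:
        for name in ("n_conditions", "n_modules", "coding_per_module",
                     "lnc_per_module"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_background_coding < 0 or self.n_background_lnc < 0:
            raise ValueError("background counts must be >= 0")
        if self.rho is not None and not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1) or None")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.nonneg not in ("shift", "exp"):
            raise ValueError("nonneg must be 'shift' or 'exp'")
        if self.n_conditions < 3:
            raise ValueError("need at least 3 conditions")


@dataclass(frozen=True)
class ModuleTruth:
    """One planted module and the terms its lncRNAs should recover."""

    name: str
    lncrna_ids: tuple[str, ...]
    coding_ids: tuple[str, ...]
    go_term: str
    pathway: tuple[str, str]  # (database_label, pathway_name)


@dataclass(frozen=True)
class FixtureTruth:
    modules: tuple[ModuleTruth, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mod in self.modules:
            genes = set(mod.lncrna_ids) | set(mod.coding_ids)
            if genes & seen:
                raise ValueError("modules share genes")
            seen |= genes


@dataclass
class FixtureBundle:
    expression: ExpressionMatrix
    catalog: GeneCatalog
    dag: OntologyDAG
    annotations: AnnotationSet  # propagated
    pathways: PathwayCollection
    truth: FixtureTruth
    config: FixtureConfig


def generate_fixture(config: FixtureConfig) -> FixtureBundle:
    """Draw one fixture from the planted-module model (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    T = config.n_conditions
    conditions = [f"tissue_{i + 1:02d}" for i in range(T)]

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    catalog: dict[str, str] = {}
    modules: list[ModuleTruth] = []

    if config.rho is not None:
        # rho = s^2 / (s^2 + sigma^2)  =>  s = sigma * sqrt(rho / (1 - rho))
        latent_scale = config.noise_sd * np.sqrt(config.rho / (1 - config.rho))
    else:
        latent_scale = 0.0

    coding_counter = lnc_counter = 0
    for mod_idx in range(config.n_modules):
        z = rng.standard_normal(T)
        coding_ids, lnc_ids = [], []
        for _ in range(config.coding_per_module):
            coding_counter += 1
            gid = f"PCG{coding_counter:05d}"
            coding_ids.append(gid)
            gene_ids.append(gid)
            catalog[gid] = "protein_coding"
            rows.append(latent_scale * z
                        + config.noise_sd * rng.standard_normal(T))
        for _ in range(config.lnc_per_module):
            lnc_counter += 1
            gid = f"LNC{lnc_counter:05d}"
            lnc_ids.append(gid)
            gene_ids.append(gid)
            catalog[gid] = "lncRNA"
            rows.append(latent_scale * z
                        + config.noise_sd * rng.standard_normal(T))
        modules.append(
            ModuleTruth(
                name=f"module{mod_idx + 1}",
                lncrna_ids=tuple(lnc_ids),
                coding_ids=tuple(coding_ids),
                go_term=f"GO:{mod_idx + 1:07d}",
                pathway=("SYNTH", f"pathway_module{mod_idx + 1}"),
            )
        )
    for _ in range(config.n_background_coding):
        coding_counter += 1
        gid = f"PCG{coding_counter:05d}"
        gene_ids.append(gid)
        catalog[gid] = "protein_coding"
        rows.append(config.noise_sd * rng.standard_normal(T))
    for _ in range(config.n_background_lnc):
        lnc_counter += 1
        gid = f"LNC{lnc_counter:05d}"
        gene_ids.append(gid)
        catalog[gid] = "lncRNA"
        rows.append(config.noise_sd * rng.standard_normal(T))

    values = np.vstack(rows)
    if config.nonneg == "shift":
        values = values - values.min()  # constant shift; correlations unchanged
    else:
        values = np.exp2(values)
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=conditions)
    )

    # ontology: one leaf per module under a shared root
    terms = {ROOT_TERM: ("planted root", "biological_process")}
    graph = nx.DiGraph()
    graph.add_node(ROOT_TERM)
    direct: dict[str, frozenset[str]] = {}
    for mod in modules:
        terms[mod.go_term] = (f"{mod.name} function", "biological_process")
        graph.add_edge(mod.go_term, ROOT_TERM, relation="is_a")
        direct[mod.go_term] = frozenset(mod.coding_ids)
    dag = OntologyDAG(terms=terms, graph=graph, obsolete=frozenset())
    annotations = propagate(dag, AnnotationSet(direct=direct, propagated={}))

    pathways = PathwayCollection(
        {mod.pathway: frozenset(mod.coding_ids) for mod in modules}
    )
    return FixtureBundle(
        expression=expression,
        catalog=GeneCatalog(catalog),
        dag=dag,
        annotations=annotations,
        pathways=pathways,
        truth=FixtureTruth(tuple(modules)),
        config=config,
    )


def write_fixture(
    bundle: FixtureBundle, directory: str | Path, force: bool = False
) -> dict[str, Path]:
    """Write a fixture as the standard text formats the parsers consume.

    Emits ``expression.tsv``, ``catalog.tsv``, ``ontology.obo``,
    ``annotations.gaf``, ``pathways.gmt`` and ``truth.json``; refuses
    to overwrite existing files unless ``force`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "catalog": directory / "catalog.tsv",
        "obo": directory / "ontology.obo",
        "gaf": directory / "annotations.gaf",
        "gmt": directory / "pathways.gmt",
        "truth": directory / "truth.json",
    }
    existing = [p for p in paths.values() if p.exists()]
    if existing and not force:
        raise FileExistsError(
            f"refusing to overwrite {existing[0]} (use force=True)"
        )

    bundle.expression.to_tsv(paths["expression"])
    bundle.catalog.to_tsv(paths["catalog"])

    with open(paths["obo"], "w") as fh:
        fh.write("format-version: 1.2\n")
        for term_id in sorted(bundle.dag.terms):
            name, namespace = bundle.dag.terms[term_id]
            fh.write(f"\n[Term]\nid: {term_id}\nname: {name}\n")
            if namespace:
                fh.write(f"namespace: {namespace}\n")
            for parent in sorted(bundle.dag.parents(term_id)):
                relation = bundle.dag.graph.edges[term_id, parent]["relation"]
                if relation == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {relation} {parent}\n")

    with open(paths["gaf"], "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for term_id in sorted(bundle.annotations.direct):
            for gene in sorted(bundle.annotations.direct[term_id]):
                cols = [
                    "SYNTH", gene, gene, "", term_id, "SYNTH:0001", "IEA",
                    "", "P", "", "", "protein", "taxon:9606", "20250101",
                    "SYNTH", "", "",
                ]
                fh.write("\t".join(cols) + "\n")

    with open(paths["gmt"], "w") as fh:
        for (database, name) in sorted(bundle.pathways.pathways):
            genes = sorted(bundle.pathways.pathways[(database, name)])
            fh.write("\t".join([name, database] + genes) + "\n")

    truth = {
        "config": asdict(bundle.config),
        "modules": [
            {
                "name": mod.name,
                "lncrna_ids": list(mod.lncrna_ids),
                "coding_ids": list(mod.coding_ids),
                "go_term": mod.go_term,
                "pathway": list(mod.pathway),
            }
            for mod in bundle.truth.modules
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def sample_null_pvalues(
    seed: int,
    n_universe: int = 5000,
    n_terms: int = 150,
    term_size_range: tuple[int, int] = (500, 2000),
    query_size: int = 300,
    n_queries: int = 20,
) -> np.ndarray:
    """Raw enrichment p-values for random queries against random terms.

    Under the null (queries drawn uniformly from the universe,
    independent of the terms) the p-values should be approximately
    uniform.  The default sizes are chosen large so the discreteness
    of the hypergeometric — which biases the sub-0.05 fraction low for
    small contingencies — is negligible.
    """
    from .enrichment import TermStats, hypergeom_pvalue

    rng = np.random.default_rng(seed)
    universe = np.arange(n_universe)
    term_sizes = rng.integers(
        term_size_range[0], term_size_range[1] + 1, size=n_terms
    )
    terms = [rng.choice(universe, size=s, replace=False) for s in term_sizes]
    term_sets = [set(t.tolist()) for t in terms]
    out = np.empty(n_terms * n_queries)
    k = 0
    for _ in range(n_queries):
        query = set(
            rng.choice(universe, size=query_size, replace=False).tolist()
        )
        for tset in term_sets:
            m = len(query & tset)
            out[k] = hypergeom_pvalue(
                TermStats(N=n_universe, M=len(tset), n=query_size, m=m)
            )
            k += 1
    return out
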