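"""Expression-matrix and gene-catalog ingestion.

The annotation workflow starts from a gene x condition matrix of
non-negative, FPKM-like expression values over a panel of conditions
(typically tissues) and a catalog assigning each gene a biotype.  The
matrix is split into an lncRNA sub-matrix and a protein-coding
sub-matrix; all downstream correlations are computed between the two
sides of that split, so the biotype assignment is load-bearing and
genes of unknown biotype are dropped rather than guessed.

Values are used as read by default.  An optional ``log2(x + 1)``
transform and an optional minimum-expression filter are exposed as
flags but disabled unless requested.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneCatalog",
    "BIOTYPE_MAP",
    "read_expression_tsv",
    "read_gene_catalog",
    "extract_catalog_from_gtf",
    "split_by_biotype",
    "log2_transform",
    "filter_low_expression",
]

#: Normalisation of GENCODE-style biotype labels onto the closed
#: vocabulary {"lncRNA", "protein_coding", "other"}.  The lncRNA family
#: covers the long non-coding classes GENCODE has used across releases.
BIOTYPE_MAP: Mapping[str, str] = {
    "protein_coding": "protein_coding",
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "antisense": "lncRNA",
    "antisense_rna": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "processed_transcript": "lncRNA",
    "3prime_overlapping_ncrna": "lncRNA",
    "3prime_overlapping_ncRNA": "lncRNA",
    "non_coding": "lncRNA",
    "macro_lncrna": "lncRNA",
    "bidirectional_promoter_lncrna": "lncRNA",
}

VALID_BIOTYPES = frozenset({"lncRNA", "protein_coding", "other"})


def normalize_biotype(label: str) -> str:
    """Map a raw biotype label onto the closed vocabulary."""
    if label in VALID_BIOTYPES:
        return label
    return BIOTYPE_MAP.get(label.strip().lower(), "other")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated gene x condition matrix of non-negative expression values.

    Parameters
    ----------
    data:
        DataFrame indexed by gene identifier with one column per
        condition.  Values must be finite and >= 0; gene and condition
        identifiers must be unique; at least 3 conditions are required
        because the Pearson significance test needs n - 2 >= 1 degrees
        of freedom.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate condition identifier: {dup!r}")
        if df.shape[1] < 3:
            raise ValueError(
                f"need at least 3 conditions, got {df.shape[1]}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value at gene {df.index[i]!r}, "
                f"condition {df.columns[j]!r}"
            )
        neg = values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                f"negative value {values[i, j]!r} at gene "
                f"{df.index[i]!r}, condition {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Row-subset preserving the matrix's own row order."""
        keep = set(gene_ids)
        rows = [g for g in self.data.index if g in keep]
        return ExpressionMatrix(self.data.loc[rows])

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: header of condition names, gene ID first column."""
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.17g")


@dataclass(frozen=True)
class GeneCatalog:
    """Map gene identifier -> biotype over a closed vocabulary."""

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {b for b in self.entries.values()} - VALID_BIOTYPES
        if bad:
            raise ValueError(f"biotype labels outside vocabulary: {sorted(bad)}")

    def biotype(self, gene_id: str) -> str:
        return self.entries.get(gene_id, "other")

    def genes_of(self, biotype: str) -> set[str]:
        return {g for g, b in self.entries.items() if b == biotype}

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene, biotype in self.entries.items():
                fh.write(f"{gene}\t{biotype}\n")


def read_expression_tsv(
    path: str | Path, delimiter: str = "\t"
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    First row is a header of condition names, first column is the gene
    identifier.  Row and column order are preserved.  Duplicate gene
    identifiers, negative values and non-numeric cells are hard errors
    naming the offending cell.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col].to_numpy(dtype=object)
        try:
            # numpy's string->float conversion is correctly rounded, so a
            # write/read cycle reproduces values bit-for-bit
            parsed[col] = np.asarray(raw, dtype=float)
        except (TypeError, ValueError):
            for gene, cell in zip(df.index, raw):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at gene "
                        f"{gene!r}, condition {col!r}"
                    ) from None
            raise
    return ExpressionMatrix(parsed)


def read_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read a two-column (gene_id, biotype) TSV into a catalog.

    Raw labels are normalised via :data:`BIOTYPE_MAP`; anything
    unrecognised becomes ``other``.  The same gene listed twice with
    conflicting biotypes is a hard error.
    """
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            gene, biotype = parts[0], normalize_biotype(parts[1])
            if gene in entries and entries[gene] != biotype:
                raise ValueError(
                    f"{path}:{lineno}: gene {gene!r} listed with conflicting "
                    f"biotypes {entries[gene]!r} and {biotype!r}"
                )
            entries[gene] = biotype
    return GeneCatalog(entries)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def extract_catalog_from_gtf(path: str | Path) -> GeneCatalog:
    """Build a catalog from the ``gene`` feature lines of a GTF file.

    Reads the ``gene_type`` (GENCODE) or ``gene_biotype`` (Ensembl)
    attribute of each gene line; non-gene features are ignored and
    unparseable attribute blocks are skipped with a warning.
    """
    entries: dict[str, str] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            biotype = attrs.get("gene_type", attrs.get("gene_biotype"))
            if gene_id is None or biotype is None:
                logger.warning(
                    "%s:%d: gene line without gene_id/gene_type, skipped",
                    path, lineno,
                )
                skipped += 1
                continue
            entries[gene_id] = normalize_biotype(biotype)
    if not entries:
        raise ValueError(f"{path}: no parseable gene feature lines")
    if skipped:
        logger.warning("%s: skipped %d unparseable gene lines", path, skipped)
    return GeneCatalog(entries)


def split_by_biotype(
    matrix: ExpressionMatrix, catalog: GeneCatalog
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition a matrix into (lncRNA, protein-coding) sub-matrices.

    Genes missing from the catalog or typed ``other`` appear in neither
    partition; the dropped count is logged.  Row order is preserved.
    An empty partition is a hard error, because the pairwise
    correlation step needs both sides.
    """
    lnc_rows, coding_rows, dropped = [], [], 0
    for gene in matrix.gene_ids:
        biotype = catalog.biotype(gene)
        if biotype == "lncRNA":
            lnc_rows.append(gene)
        elif biotype == "protein_coding":
            coding_rows.append(gene)
        else:
            dropped += 1
    if dropped:
        logger.warning(
            "split_by_biotype: dropped %d gene(s) absent from the catalog "
            "or with biotype 'other'", dropped,
        )
    if not lnc_rows:
        raise ValueError("no lncRNA genes after the biotype split")
    if not coding_rows:
        raise ValueError("no protein-coding genes after the biotype split")
    return matrix.subset(lnc_rows), matrix.subset(coding_rows)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return a matrix of ``log2(x + 1)`` values (optional, off by default)."""
    return ExpressionMatrix(np.log2(matrix.data + 1.0))


def filter_low_expression(
    matrix: ExpressionMatrix, min_value: float = 1.0, min_conditions: int = 1
) -> ExpressionMatrix:
    """Keep genes expressed at >= ``min_value`` in >= ``min_conditions``.

    Disabled by default in the pipeline; provided for users who want a
    detectability prefilter before correlation.
    """
    mask = (matrix.data >= min_value).sum(axis=1) >= min_conditions
    kept = matrix.data.loc[mask]
    if kept.shape[0] == 0:
        raise ValueError("expression filter removed every gene")
    logger.info(
        "expression filter kept %d of %d genes", kept.shape[0], matrix.n_genes
    )
    return ExpressionMatrix(kept)
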