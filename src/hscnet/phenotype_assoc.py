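"""Gene-phenotype annotation model (MGI-style knockout phenotype data).

Two analyses are supported on a binary gene x phenotype incidence matrix:

* set-vs-phenotype enrichment — is a gene set (say, a stem-cell fingerprint)
  over-represented among genes annotated to a phenotype category (say,
  "nervous system")? Each phenotype column is treated as a comparator set and
  scored with the full overlap statistics (Z, Fisher p, odds ratio).
* phenotype co-annotation correlation — the phi coefficient (Pearson
  correlation of binary indicator columns) between every pair of phenotype
  categories, the matrix behind a co-annotation heatmap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_sets import GeneSet, Universe, restrict_universe
from .overlap_stats import OverlapResult, enrich

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationMatrix", "CorrelationMatrix",
    "read_annotations", "annotation_set",
    "set_phenotype_enrichment", "phenotype_correlation",
    "write_correlation_tsv",
]


@dataclass(frozen=True)
class AnnotationMatrix:
    """Binary gene x phenotype incidence matrix.

    ``incidence`` is a pandas DataFrame with genes as the index and phenotype
    terms as columns; entries are 0/1.
    """

    incidence: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.incidence
        if df.index.has_duplicates:
            raise ValueError("duplicate gene symbols in annotation matrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicate phenotype labels in annotation matrix")
        vals = df.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        object.__setattr__(self, "incidence", df.astype(np.int8))

    @property
    def genes(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.incidence.columns)

    def universe(self, name: str = "annotated_genes") -> Universe:
        """The genes present in the matrix, as an enrichment universe."""
        return Universe(name=name, symbols=frozenset(self.genes))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric phenotype x phenotype correlation with a definedness mask.

    ``values[i, j]`` is NaN exactly where ``defined[i, j]`` is False (a
    constant indicator column makes the coefficient undefined); downstream
    consumers check the mask instead of testing for NaN.
    """

    phenotypes: tuple[str, ...]
    values: np.ndarray
    defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.phenotypes),
                            columns=list(self.phenotypes))


def read_annotations(path) -> AnnotationMatrix:
    """Read two-column (gene_symbol, phenotype_term) TSV into an incidence matrix.

    Duplicate pairs collapse to a single 1. Lines starting with '#' and blank
    lines are skipped; CRLF tolerated.
    """
    genes, phens = [], []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"line {lineno}: expected exactly 2 tab-separated "
                                 "columns (gene_symbol, phenotype_term)")
            genes.append(fields[0].strip())
            phens.append(fields[1].strip())
    if not genes:
        log.warning("annotation file %s is empty", path)
        return AnnotationMatrix(incidence=pd.DataFrame())
    df = pd.crosstab(pd.Index(genes, name="gene"),
                     pd.Index(phens, name="phenotype"))
    df = (df > 0).astype(np.int8)
    df = df.sort_index(axis=0).sort_index(axis=1)
    log.info("read %d genes x %d phenotypes from %s",
             df.shape[0], df.shape[1], path)
    return AnnotationMatrix(incidence=df)


def annotation_set(matrix: AnnotationMatrix, phenotype: str) -> GeneSet:
    """The genes annotated to one phenotype column, as a GeneSet."""
    if phenotype not in matrix.incidence.columns:
        raise KeyError(f"unknown phenotype {phenotype!r}; available: "
                       f"{sorted(matrix.incidence.columns)}")
    col = matrix.incidence[phenotype]
    return GeneSet(name=phenotype,
                   symbols=frozenset(col.index[col == 1]))


def set_phenotype_enrichment(gene_set: GeneSet, matrix: AnnotationMatrix,
                             universe: Universe | None = None,
                             phenotypes: list[str] | None = None,
                             **options) -> list[OverlapResult]:
    """Enrichment of a gene set against each phenotype annotation set.

    The universe defaults to the genes present in the annotation matrix — the
    genes actually *tested* for phenotypes — so that enrichment is not
    confounded with testedness. Results are ordered by phenotype label.
    """
    if universe is None:
        universe = matrix.universe()
    fixed = restrict_universe(universe, gene_set)
    wanted = sorted(matrix.phenotypes) if phenotypes is None else sorted(phenotypes)
    results = []
    for term in wanted:
        comparator = restrict_universe(universe, annotation_set(matrix, term))
        results.append(enrich(fixed, comparator, universe, **options))
    return results


def phenotype_correlation(matrix: AnnotationMatrix,
                          measure: str = "phi") -> CorrelationMatrix:
    """Pairwise phi coefficients between phenotype indicator columns.

    phi is the Pearson correlation of two binary vectors, equivalently
    (n11*n00 - n10*n01) / sqrt(r1*r0*c1*c0) from the 2x2 co-annotation table.
    Genes with all-zero rows are retained (co-absence is informative).
    Pairs involving a constant column are undefined and flagged via the
    ``defined`` mask rather than propagating NaN silently.
    """
    if measure != "phi":
        raise ValueError(f"unknown correlation measure {measure!r}")
    p = len(matrix.phenotypes)
    if p < 2:
        raise ValueError("phenotype correlation needs at least 2 phenotypes")
    X = matrix.incidence.to_numpy(dtype=np.int64)
    g = X.shape[0]
    s = X.sum(axis=0)                       # genes annotated per phenotype
    C = X.T @ X                             # co-annotation counts n11
    cov = g * C - np.outer(s, s)            # g^2 * covariance
    var = s * (g - s)                       # g^2 * variance per column
    denom = np.sqrt(np.outer(var, var).astype(float))
    degenerate = var == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = cov / denom
    values = np.clip(values, -1.0, 1.0)
    defined = ~(degenerate[:, None] | degenerate[None, :])
    values[~defined] = np.nan
    np.fill_diagonal(values, np.where(degenerate, np.nan, 1.0))
    values = (values + values.T) / 2.0      # enforce exact symmetry
    if degenerate.any():
        bad = [matrix.phenotypes[i] for i in np.flatnonzero(degenerate)]
        log.warning("degenerate (constant) phenotype columns: %s", bad)
    return CorrelationMatrix(phenotypes=tuple(matrix.phenotypes),
                             values=values, defined=defined)


def write_correlation_tsv(corr: CorrelationMatrix, path) -> None:
    corr.to_frame().to_csv(path, sep="\t", index=True,
                           index_label="phenotype", float_format="%.10g")
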