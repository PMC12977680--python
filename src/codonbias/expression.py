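"""Count normalisation and expression-weighted codon usage.

A tissue's codon demand is estimated by weighting each gene's per-CDS codon
*frequency* by its normalised expression in that tissue and summing over
genes, then scaling the 64-slot result so its maximum is 1.  Normalisation
uses the median-of-ratios size-factor formula: each column is divided by the
median, over genes detected in every sample, of its ratio to a
geometric-mean pseudo-reference column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

from .codons import (
    CodonUsageProfile,
    ProfileKind,
    codon_frequency,
    count_elongator_codons,
)

if TYPE_CHECKING:  # pragma: no cover
    from .sequence_io import TranscriptCatalog

logger = logging.getLogger("codonbias")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Non-negative count matrix (rows = transcripts/genes, columns =
    samples/tissues) with optional per-column size factors."""

    data: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate row id(s): {', '.join(map(str, dupes[:5]))}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate column names")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric cells")
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        if (values < 0).any():
            raise ValueError("expression matrix contains negative counts")
        if self.size_factors is not None:
            sf = self.size_factors.reindex(self.data.columns)
            if sf.isna().any() or (sf <= 0).any():
                raise ValueError("size factors must be positive and cover every column")
            self.size_factors = sf.astype(float)

    @property
    def row_ids(self) -> pd.Index:
        return self.data.index

    @property
    def col_ids(self) -> pd.Index:
        return self.data.columns


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with a sample-name header row and ids in the first column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    try:
        table = table.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in expression table ({exc})") from exc
    return ExpressionMatrix(table)


# ---------------------------------------------------------------------------
# Median-of-ratios normalisation
# ---------------------------------------------------------------------------


def median_of_ratios_size_factors(
    matrix: ExpressionMatrix, max_zero_columns: int = 0
) -> pd.Series:
    """Estimate per-column size factors by the median-of-ratios formula.

    For column j, ``s_j`` is the median over reference rows of
    ``counts[i, j] / geometric_mean(counts[i, :])``.  Reference rows are rows
    with at most ``max_zero_columns`` zeros (default: none, i.e. genes
    detected in every sample); with a relaxed threshold the geometric mean is
    taken over the positive entries and zero cells contribute no ratio.

    The estimated factors are attached to ``matrix.size_factors`` and
    returned.
    """
    X = matrix.data.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("size-factor estimation needs at least two columns")
    n_zero = (X == 0).sum(axis=1)
    ref_rows = n_zero <= max_zero_columns
    if not ref_rows.any():
        raise ValueError(
            "no reference rows with all counts > 0; relax max_zero_columns to use "
            "a pseudo-reference computed on rows with some zeros"
        )
    R = X[ref_rows]
    with np.errstate(divide="ignore"):
        logs = np.where(R > 0, np.log(R), np.nan)
    pseudo_ref = np.exp(np.nanmean(logs, axis=1))
    with np.errstate(invalid="ignore"):
        ratios = R / pseudo_ref[:, None]
    ratios[R == 0] = np.nan
    factors = np.nanmedian(ratios, axis=0)
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValueError("degenerate size factors; check for all-zero columns")
    series = pd.Series(factors, index=matrix.col_ids, name="size_factor")
    matrix.size_factors = series
    return series


def normalize_counts(matrix: ExpressionMatrix, pre_normalized: bool = False) -> ExpressionMatrix:
    """Divide each column by its size factor; factors reset to 1.

    ``pre_normalized=True`` passes the counts through untouched (the upstream
    pipeline already normalised them), which makes the operation idempotent
    either way.
    """
    ones = pd.Series(1.0, index=matrix.col_ids, name="size_factor")
    if pre_normalized:
        return ExpressionMatrix(matrix.data.astype(float).copy(), ones)
    if matrix.size_factors is None:
        raise ValueError(
            "size factors are unset; run median_of_ratios_size_factors first "
            "or pass pre_normalized=True"
        )
    return ExpressionMatrix(matrix.data / matrix.size_factors, ones)


# ---------------------------------------------------------------------------
# Expression-weighted usage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueUsage:
    """Expression-weighted codon usage of one tissue.

    ``raw_usage[c] = sum_g count[g, tissue] * frequency_g[c]`` over the genes
    used; ``scaled_usage`` is the same vector divided by its maximum across
    all 64 codons.
    """

    tissue: str
    raw_usage: CodonUsageProfile
    scaled_usage: CodonUsageProfile | None
    n_genes_used: int


def _gene_frequency_table(catalog: "TranscriptCatalog") -> tuple[pd.Index, np.ndarray, dict[str, str]]:
    """Per-gene 64-slot frequency rows plus a transcript->gene alias map."""
    genes: list[str] = []
    rows: list[np.ndarray] = []
    alias: dict[str, str] = {}
    for rec in catalog:
        vec = count_elongator_codons(rec, strict=False)
        if vec.total_elongator == 0:
            logger.warning("skipping %s: no countable elongator codons", rec.transcript_id)
            continue
        genes.append(rec.gene_id)
        rows.append(codon_frequency(vec).values)
        alias[rec.transcript_id] = rec.gene_id
    return pd.Index(genes), np.array(rows), alias


def weighted_codon_usage(
    catalog: "TranscriptCatalog",
    matrix: ExpressionMatrix,
    tissue: str,
    gene_list: Iterable[str] | None = None,
    id_map: Mapping[str, str] | None = None,
) -> TissueUsage:
    """Expression-weighted codon usage for one tissue column.

    Matrix rows are resolved to catalog genes by gene id, then by transcript
    id, then through ``id_map``; unresolvable rows are skipped with a logged
    count (annotation mismatches are routine, not fatal).  If ``gene_list``
    is given (e.g. the tissue's differentially expressed genes) the sum is
    restricted to it.
    """
    if tissue not in matrix.col_ids:
        raise ValueError(f"tissue column {tissue!r} not in expression matrix")
    genes, freq_rows, alias = _gene_frequency_table(catalog)
    if id_map:
        alias.update(id_map)
    gene_pos = {g: i for i, g in enumerate(genes)}

    counts = matrix.data[tissue]
    weights = np.zeros(len(genes), dtype=float)
    used: set[str] = set()
    n_skipped = 0
    wanted = set(gene_list) if gene_list is not None else None
    for row_id, value in counts.items():
        gene = row_id if row_id in gene_pos else alias.get(row_id)
        if gene is None or gene not in gene_pos:
            n_skipped += 1
            continue
        if wanted is not None and gene not in wanted and row_id not in wanted:
            continue
        weights[gene_pos[gene]] += float(value)
        used.add(gene)
    if n_skipped:
        logger.info("weighted_codon_usage[%s]: skipped %d unmatched rows", tissue, n_skipped)
    if not used:
        raise ValueError(f"no expression rows matched the catalog for tissue {tissue!r}")
    raw = CodonUsageProfile(weights @ freq_rows, ProfileKind.WEIGHTED_USAGE)
    return TissueUsage(tissue, raw, None, len(used))


def max_normalize_usage(usage: TissueUsage) -> TissueUsage:
    """Fill ``scaled_usage``: raw usage divided by its maximum over all 64
    codons, so values lie in [0, 1]."""
    return replace(usage, scaled_usage=usage.raw_usage.max_normalized())
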