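"""Tissue-versus-genome codon usage bias and pipeline orchestration.

The bias of codon ``c`` in a tissue is the ratio of the tissue's
max-normalised usage to the genome's max-normalised usage at that codon.
Computing the ratio on max-normalised vectors makes it independent of
sequencing depth and of the absolute size of the CDS set; codons absent from
the genome baseline have no defined ratio and are reported as such rather
than as infinities.
"""

from __future__ import annotations

import contextlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .codons import (
    CODONS,
    GENETIC_CODE,
    STOP_CODONS,
    CodonUsageProfile,
    ProfileKind,
    aggregate_genome_usage,
    validate_codon_set,
)
from .expression import (
    ExpressionMatrix,
    TissueUsage,
    max_normalize_usage,
    median_of_ratios_size_factors,
    normalize_counts,
    read_expression_table,
    weighted_codon_usage,
)
from .sequence_io import (
    read_cds_fasta,
    read_gene_list,
    select_longest_isoform,
    validate_cds,
)

logger = logging.getLogger("codonbias")

#: Threonine codons decoded by tRNA-Thr-AGT (directly, and via wobble).
DEFAULT_FOCUS_SET = frozenset({"ACT", "ACC"})

#: A tissue is flagged only when every focus codon exceeds the genome baseline
#: by more than this factor; the 10% margin guards against sampling noise in
#: the ratio (set to 1.0 for a strict greater-than-baseline rule).
DEFAULT_FLAG_THRESHOLD = 1.1


# ---------------------------------------------------------------------------
# Ratios
# ---------------------------------------------------------------------------


def _tissue_vector(tissue: TissueUsage, on: str) -> np.ndarray:
    if on == "scaled":
        if tissue.scaled_usage is None:
            raise ValueError(f"tissue {tissue.tissue!r} has no scaled usage; max-normalise first")
        return tissue.scaled_usage.values
    if on == "frequency":
        total = tissue.raw_usage.values.sum()
        if total <= 0:
            raise ValueError(f"tissue {tissue.tissue!r} has all-zero usage")
        return tissue.raw_usage.values / total
    raise ValueError(f"unknown ratio mode {on!r} (expected 'scaled' or 'frequency')")


def _genome_vector(genome: CodonUsageProfile, on: str) -> np.ndarray:
    if on == "scaled":
        if genome.kind is not ProfileKind.MAX_NORMALIZED:
            genome = genome.max_normalized()
        return genome.values
    total = genome.values.sum()
    return genome.values / total if total > 0 else genome.values


def usage_bias_ratio(
    tissue: TissueUsage, genome: CodonUsageProfile, on: str = "scaled"
) -> tuple[np.ndarray, frozenset[str]]:
    """Per-codon tissue/genome ratio plus the set of undefined codons.

    Both vectors are compared on the max-normalised scale by default
    (``on="frequency"`` compares sense-codon frequencies instead, for
    sensitivity analysis).  Slots where the genome usage is zero carry NaN
    and are returned in the undefined set.
    """
    g = _genome_vector(genome, on)
    if not (g > 0).any():
        raise ValueError("genome usage profile is all zero")
    t = _tissue_vector(tissue, on)
    ratio = np.full(64, np.nan)
    defined = g > 0
    ratio[defined] = t[defined] / g[defined]
    undefined = frozenset(c for c, d in zip(CODONS, defined) if not d)
    return ratio, undefined


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiasReport:
    """Per-codon tissue/genome usage ratios across tissues.

    ``focus_flags[t]`` is True when every codon of ``focus_set`` is defined
    and exceeds ``flag_threshold`` in tissue ``t``.
    """

    tissues: tuple[str, ...]
    ratios: pd.DataFrame  # 64 codons x tissues, NaN where undefined
    undefined_codons: dict[str, frozenset[str]]
    focus_set: frozenset[str]
    focus_flags: dict[str, bool]
    flag_threshold: float
    genome_scaled: pd.Series
    tissue_scaled: pd.DataFrame
    n_genes_used: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy 64-row table: codon, amino_acid, genome_scaled, then one
        scaled-usage and one ratio column per tissue."""
        out = pd.DataFrame(
            {
                "codon": list(CODONS),
                "amino_acid": [GENETIC_CODE[c] for c in CODONS],
                "genome_scaled": self.genome_scaled.to_numpy(),
            }
        )
        for t in self.tissues:
            out[f"{t}_scaled"] = self.tissue_scaled[t].to_numpy()
        for t in self.tissues:
            out[f"{t}_ratio"] = self.ratios[t].to_numpy()
        return out

    def to_dict(self) -> dict:
        return {
            "tissues": list(self.tissues),
            "focus_set": sorted(self.focus_set),
            "flag_threshold": self.flag_threshold,
            "focus_flags": {t: bool(self.focus_flags[t]) for t in self.tissues},
            "focus_ratios": {
                t: {
                    c: (None if np.isnan(v) else float(v))
                    for c in sorted(self.focus_set)
                    for v in [self.ratios.loc[c, t]]
                }
                for t in self.tissues
            },
            "undefined_codons": {t: sorted(self.undefined_codons[t]) for t in self.tissues},
            "n_genes_used": {t: int(n) for t, n in self.n_genes_used.items()},
        }


def compare_tissues(
    usages: Sequence[TissueUsage],
    genome: CodonUsageProfile,
    focus_set: Iterable[str] = DEFAULT_FOCUS_SET,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
    on: str = "scaled",
) -> BiasReport:
    """Build a :class:`BiasReport` for one or more tissues against the genome
    baseline.  Stop codons cannot be focus codons (they are never decoded by
    elongating tRNAs)."""
    if not usages:
        raise ValueError("at least one tissue usage is required")
    focus = validate_codon_set(focus_set)
    stops = focus & STOP_CODONS
    if stops:
        raise ValueError(f"stop codons cannot be in the focus set: {sorted(stops)}")
    names = [u.tissue for u in usages]
    if len(set(names)) != len(names):
        raise ValueError("duplicate tissue names")

    genome_scaled = _genome_vector(genome, on)
    ratio_cols: dict[str, np.ndarray] = {}
    scaled_cols: dict[str, np.ndarray] = {}
    undefined: dict[str, frozenset[str]] = {}
    flags: dict[str, bool] = {}
    for u in usages:
        ratio, undef = usage_bias_ratio(u, genome, on=on)
        ratio_cols[u.tissue] = ratio
        scaled_cols[u.tissue] = _tissue_vector(u, on)
        undefined[u.tissue] = undef
        focus_vals = [ratio[CODONS.index(c)] for c in focus]
        flags[u.tissue] = bool(
            all(np.isfinite(v) and v > flag_threshold for v in focus_vals)
        )
    index = pd.Index(CODONS, name="codon")
    return BiasReport(
        tissues=tuple(names),
        ratios=pd.DataFrame(ratio_cols, index=index),
        undefined_codons=undefined,
        focus_set=focus,
        focus_flags=flags,
        flag_threshold=flag_threshold,
        genome_scaled=pd.Series(genome_scaled, index=index, name="genome_scaled"),
        tissue_scaled=pd.DataFrame(scaled_cols, index=index),
        n_genes_used={u.tissue: u.n_genes_used for u in usages},
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


class PipelineError(RuntimeError):
    """Error raised by :func:`run_pipeline`, labelled with the failing stage."""


@contextlib.contextmanager
def _stage(name: str) -> Iterator[None]:
    logger.info("[%s] start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[{name}] {exc}") from exc


@dataclass
class PipelineConfig:
    """Inputs and options for the end-to-end bias pipeline."""

    cds_fasta: str
    counts: str
    out_dir: str
    tissues: tuple[str, ...] | None = None  # default: every counts column
    gene_lists: Mapping[str, str] = field(default_factory=dict)  # tissue -> path
    focus_set: tuple[str, ...] = tuple(sorted(DEFAULT_FOCUS_SET))
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD
    pre_normalized: bool = False
    max_zero_columns: int = 0
    ratio_on: str = "scaled"
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tissues" in raw and raw["tissues"] is not None:
            raw["tissues"] = tuple(raw["tissues"])
        if "focus_set" in raw:
            raw["focus_set"] = tuple(raw["focus_set"])
        return cls(**raw)


_FLOAT_FMT = "%.12g"


def run_pipeline(config: PipelineConfig) -> BiasReport:
    """Run the full analysis: read CDS, validate, reduce to longest isoforms,
    build the genome baseline, normalise counts, weight codon usage per
    tissue, max-normalise, and compare to the genome.

    All tables are written to ``config.out_dir``; rerunning on identical
    inputs reproduces byte-identical files.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("read_cds"):
        catalog = read_cds_fasta(config.cds_fasta)
        if len(catalog) == 0:
            raise ValueError("CDS FASTA contains no records")

    with _stage("validate"):
        reports = [validate_cds(rec) for rec in catalog]
        n_flagged = sum(1 for r in reports if not r.clean)
        logger.info("[validate] %d/%d CDS carry advisory flags", n_flagged, len(reports))
        if config.strict:
            from .sequence_io import ValidationFlag

            fatal = {ValidationFlag.NOT_MULTIPLE_OF_3, ValidationFlag.INTERNAL_STOP}
            bad = [r.transcript_id for r in reports if r.flags & fatal]
            if bad:
                raise ValueError(f"strict mode: frameshifted or internally stopped CDS: {bad[:5]}")

    with _stage("longest_isoform"):
        catalog = select_longest_isoform(catalog)

    with _stage("genome_usage"):
        genome_counts, genome_freq = aggregate_genome_usage(catalog)
        genome_scaled = genome_freq.max_normalized()

    with _stage("read_counts"):
        matrix = read_expression_table(config.counts)
        tissues = config.tissues or tuple(matrix.col_ids)
        missing = [t for t in tissues if t not in matrix.col_ids]
        if missing:
            raise ValueError(f"tissue column(s) not in counts table: {missing}")

    with _stage("normalize"):
        if not config.pre_normalized:
            size_factors = median_of_ratios_size_factors(
                matrix, max_zero_columns=config.max_zero_columns
            )
        else:
            size_factors = pd.Series(1.0, index=matrix.col_ids, name="size_factor")
        matrix = normalize_counts(matrix, pre_normalized=config.pre_normalized)

    usages: list[TissueUsage] = []
    for tissue in tissues:
        with _stage(f"usage:{tissue}"):
            gene_list = None
            if tissue in config.gene_lists:
                gene_list = read_gene_list(config.gene_lists[tissue])
            usage = weighted_codon_usage(catalog, matrix, tissue, gene_list=gene_list)
            usages.append(max_normalize_usage(usage))

    with _stage("bias"):
        report = compare_tissues(
            usages,
            genome_scaled,
            focus_set=config.focus_set,
            flag_threshold=config.flag_threshold,
            on=config.ratio_on,
        )

    with _stage("write"):
        genome_table = pd.DataFrame(
            {
                "codon": list(CODONS),
                "amino_acid": [GENETIC_CODE[c] for c in CODONS],
                "count": genome_counts.counts,
                "frequency": genome_freq.values,
                "scaled": genome_scaled.values,
            }
        )
        genome_table.to_csv(out_dir / "genome_usage.tsv", sep="\t", index=False,
                            float_format=_FLOAT_FMT)
        for usage in usages:
            per_tissue = pd.DataFrame(
                {
                    "codon": list(CODONS),
                    "raw_usage": usage.raw_usage.values,
                    "scaled_usage": usage.scaled_usage.values,
                }
            )
            per_tissue.to_csv(out_dir / f"{usage.tissue}_usage.tsv", sep="\t",
                              index=False, float_format=_FLOAT_FMT)
            sidecar = {
                "tissue": usage.tissue,
                "n_genes_used": usage.n_genes_used,
                "size_factors": {c: float(size_factors[c]) for c in matrix.col_ids},
            }
            (out_dir / f"{usage.tissue}_usage.json").write_text(
                json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
            )
        report.to_frame().to_csv(out_dir / "bias_report.tsv", sep="\t", index=False,
                                 float_format=_FLOAT_FMT)
        (out_dir / "bias_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    logger.info("[done] wrote %s", out_dir)
    return report
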