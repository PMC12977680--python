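"""Codon arithmetic on coding sequences.

The counting rule throughout this package is the *elongator-codon* rule: the
initiator codon is excluded (it is decoded by the initiator tRNA, not by an
elongating one) and a terminal stop triplet, when present, is excluded as well
(stops are decoded by release factors).  Counts are kept in a fixed 64-slot
vector in lexicographic codon order (AAA .. TTT) so that downstream
"across all 64 codons" normalisations are literal; the three stop slots are
zero for any clean CDS.

Codons containing ambiguous bases (anything outside A/C/G/T) are skipped and
removed from the denominator rather than guessed at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

if TYPE_CHECKING:  # pragma: no cover
    from .sequence_io import CodingSequence, TranscriptCatalog

logger = logging.getLogger("codonbias")

# ---------------------------------------------------------------------------
# Codon tables and fixed index order
# ---------------------------------------------------------------------------

#: All 64 codons in lexicographic order over the alphabet A < C < G < T.
CODONS: tuple[str, ...] = tuple("".join(c) for c in product("ACGT", repeat=3))

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})

#: The 61 sense codons, in the same lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

START_CODON = "ATG"

_standard = CodonTable.unambiguous_dna_by_name["Standard"]

#: codon -> one-letter amino acid, with '*' for the three stops.
GENETIC_CODE: dict[str, str] = {
    **{c: _standard.forward_table[c] for c in SENSE_CODONS},
    **{c: "*" for c in STOP_CODONS},
}

#: amino acid -> synonymous sense codons (lexicographic order within family).
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    SYNONYMOUS_FAMILIES.setdefault(GENETIC_CODE[_c], tuple())
    SYNONYMOUS_FAMILIES[GENETIC_CODE[_c]] += (_c,)

_SENSE_MASK = np.array([c not in STOP_CODONS for c in CODONS], dtype=bool)
_STOP_IDX = frozenset(CODON_INDEX[c] for c in STOP_CODONS)

# byte -> base value lookup (A=0, C=1, G=2, T=3; -1 = ambiguous)
_BASE_VAL = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_VAL[ord(_b)] = _i


def validate_codon_set(codon_set: Iterable[str]) -> frozenset[str]:
    """Return ``codon_set`` as a frozenset, rejecting anything that is not a
    length-3 string over A/C/G/T."""
    codons = frozenset(codon_set)
    if not codons:
        raise ValueError("codon set must be non-empty")
    bad = sorted(c for c in codons if c not in CODON_INDEX)
    if bad:
        raise ValueError(f"invalid codon(s): {', '.join(bad)}")
    return codons


def codon_index_array(seq: str) -> np.ndarray:
    """Map a DNA string onto in-frame codon indices.

    Returns an int64 array of length ``len(seq) // 3``; a codon containing a
    non-ACGT character maps to -1.  Trailing bases beyond the last complete
    codon are ignored.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = len(raw) // 3
    if n == 0:
        return np.empty(0, dtype=np.int64)
    vals = _BASE_VAL[raw[: 3 * n]].reshape(n, 3)
    idx = vals[:, 0] * 16 + vals[:, 1] * 4 + vals[:, 2]
    idx[(vals < 0).any(axis=1)] = -1
    return idx


# ---------------------------------------------------------------------------
# Count vectors and usage profiles
# ---------------------------------------------------------------------------


class ProfileKind(str, Enum):
    FREQUENCY = "FREQUENCY"
    WEIGHTED_USAGE = "WEIGHTED_USAGE"
    MAX_NORMALIZED = "MAX_NORMALIZED"


@dataclass(frozen=True)
class CodonCountVector:
    """64-slot integer vector of elongator-codon counts.

    ``total_elongator`` is the number of counted *sense* codons; internal stop
    triplets (possible only on unvalidated input) land in their own slots but
    do not contribute to the total.
    """

    counts: np.ndarray
    total_elongator: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (64,):
            raise ValueError("counts must be a 64-slot vector")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        if int(counts[_SENSE_MASK].sum()) != self.total_elongator:
            raise ValueError("total_elongator must equal the sense-codon sum")

    @classmethod
    def zero(cls) -> "CodonCountVector":
        return cls(np.zeros(64, dtype=np.int64), 0)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "CodonCountVector":
        counts = np.zeros(64, dtype=np.int64)
        for codon, n in mapping.items():
            counts[CODON_INDEX[codon]] = n
        return cls(counts, int(counts[_SENSE_MASK].sum()))

    def __add__(self, other: "CodonCountVector") -> "CodonCountVector":
        return CodonCountVector(
            self.counts + other.counts, self.total_elongator + other.total_elongator
        )

    def __getitem__(self, codon: str) -> int:
        return int(self.counts[CODON_INDEX[codon]])

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CODONS), name="count")


@dataclass(frozen=True)
class CodonUsageProfile:
    """64-slot non-negative real vector with a tag for what it measures.

    FREQUENCY profiles sum to 1 over the sense codons; MAX_NORMALIZED
    profiles peak at exactly 1 (unless identically zero).
    """

    values: np.ndarray
    kind: ProfileKind

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (64,):
            raise ValueError("values must be a 64-slot vector")
        if (values < 0).any():
            raise ValueError("values must be non-negative")
        object.__setattr__(self, "values", values)

    def __getitem__(self, codon: str) -> float:
        return float(self.values[CODON_INDEX[codon]])

    def max_normalized(self) -> "CodonUsageProfile":
        """Scale so the maximum slot is exactly 1 ("scaling the values
        between 0 and 1"); an all-zero profile stays zero with a warning."""
        peak = float(self.values.max())
        if peak <= 0.0:
            logger.warning("max-normalising an all-zero usage profile")
            return CodonUsageProfile(np.zeros(64), ProfileKind.MAX_NORMALIZED)
        return CodonUsageProfile(self.values / peak, ProfileKind.MAX_NORMALIZED)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(CODONS), name=self.kind.value.lower())


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def count_elongator_codons(cds: "CodingSequence | str", strict: bool = True) -> CodonCountVector:
    """Count the codons of one CDS that are translated by elongating tRNAs.

    The first codon is always excluded; the terminal codon is excluded if and
    only if it is a stop triplet.  Codons containing ambiguous bases are
    skipped and do not enter ``total_elongator``.

    In strict mode a sequence whose length is not a multiple of 3, or which is
    shorter than two codons (no elongator codons at all), is an error; in
    lenient mode the sequence is truncated to frame and a too-short sequence
    yields a zero vector.
    """
    seq = cds if isinstance(cds, str) else cds.seq
    if len(seq) % 3 != 0:
        if strict:
            raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    idx = codon_index_array(seq)
    if len(idx) < 2:
        if strict:
            raise ValueError("CDS has no elongator codons (shorter than 2 codons)")
        return CodonCountVector.zero()
    body = idx[1:]
    if int(body[-1]) in _STOP_IDX:
        body = body[:-1]
    body = body[body >= 0]  # drop ambiguous codons
    counts = np.bincount(body, minlength=64).astype(np.int64)
    return CodonCountVector(counts, int(counts[_SENSE_MASK].sum()))


def codon_frequency(counts: CodonCountVector) -> CodonUsageProfile:
    """Per-CDS codon frequency: each slot divided by the elongator total."""
    if counts.total_elongator <= 0:
        raise ValueError("cannot compute frequencies with zero elongator codons")
    return CodonUsageProfile(
        counts.counts / float(counts.total_elongator), ProfileKind.FREQUENCY
    )


def codon_set_fraction(
    profile_or_counts: CodonUsageProfile | CodonCountVector,
    codon_set: Iterable[str],
) -> float:
    """Summed frequency of a codon set (e.g. the ACT/ACC threonine codons)."""
    codons = validate_codon_set(codon_set)
    if isinstance(profile_or_counts, CodonCountVector):
        profile = codon_frequency(profile_or_counts)
    else:
        profile = profile_or_counts
    return float(sum(profile[c] for c in codons))


# ---------------------------------------------------------------------------
# Enrichment ranking and genome baseline
# ---------------------------------------------------------------------------

RANK_COLUMNS = ["gene_id", "transcript_id", "total_elongator", "set_count", "set_fraction"]


def rank_by_codon_enrichment(
    catalog: "TranscriptCatalog",
    codon_set: Iterable[str] = frozenset({"ACT", "ACC"}),
    min_elongator: int = 50,
    strict: bool = False,
) -> pd.DataFrame:
    """Rank genes by the fraction of their elongator codons in ``codon_set``.

    Expects one representative CDS per gene (see
    :func:`codonbias.sequence_io.select_longest_isoform`).  Genes with fewer
    than ``min_elongator`` countable codons are dropped: fractions on very
    short CDS are dominated by sampling noise.  Rows are sorted by set
    fraction (desc), then elongator total (desc), then gene id (asc).
    """
    codons = validate_codon_set(codon_set)
    if len(catalog) == 0:
        raise ValueError("cannot rank an empty catalog")
    set_idx = [CODON_INDEX[c] for c in sorted(codons)]
    rows = []
    for rec in catalog:
        vec = count_elongator_codons(rec, strict=strict)
        if vec.total_elongator < min_elongator:
            continue
        set_count = int(vec.counts[set_idx].sum())
        rows.append(
            (
                rec.gene_id,
                rec.transcript_id,
                vec.total_elongator,
                set_count,
                set_count / vec.total_elongator,
            )
        )
    table = pd.DataFrame(rows, columns=RANK_COLUMNS)
    table = table.sort_values(
        by=["set_fraction", "total_elongator", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def aggregate_genome_usage(
    catalog: "TranscriptCatalog", strict: bool = False
) -> tuple[CodonCountVector, CodonUsageProfile]:
    """Genome-baseline codon counts and frequency: the elementwise sum of
    elongator counts over every CDS in the catalog, and its frequency.

    The catalog should already be reduced to one isoform per gene.
    """
    if len(catalog) == 0:
        raise ValueError("cannot aggregate an empty catalog")
    total = np.zeros(64, dtype=np.int64)
    for rec in catalog:
        total += count_elongator_codons(rec, strict=strict).counts
    agg = CodonCountVector(total, int(total[_SENSE_MASK].sum()))
    if agg.total_elongator == 0:
        raise ValueError("no countable elongator codons in the catalog")
    return agg, codon_frequency(agg)
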