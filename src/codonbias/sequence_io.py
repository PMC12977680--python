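"""Reading and validating CDS FASTA and tabular inputs.

Handles the two common CDS-FASTA header dialects (an explicit ``gene=``
attribute, or a bare transcript id whose isoform suffix implies the gene),
reduces multi-isoform genes to a single representative CDS (the longest), and
performs advisory CDS validation: real annotation releases contain CDS that
lack a start, run past a stop or are out of frame, and the caller decides
whether that is fatal.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterator, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import STOP_CODONS, codon_index_array, _STOP_IDX


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    """Open plain or gzip-compressed text transparently."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodingSequence:
    """One transcript's CDS with its transcript and gene identifiers.

    The sequence is upper-cased and RNA 'U' is mapped to 'T' on construction;
    any residual non-ACGT characters are kept and treated as ambiguous by the
    counting rules.
    """

    transcript_id: str
    gene_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper().replace("U", "T"))

    @property
    def length_nt(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranscriptCatalog:
    """Ordered, uniquely-keyed collection of coding sequences."""

    records: tuple[CodingSequence, ...]
    by_gene: dict[str, list[str]] = field(init=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        by_gene: dict[str, list[str]] = {}
        for rec in self.records:
            if rec.transcript_id in seen:
                raise ValueError(f"duplicate transcript id: {rec.transcript_id}")
            seen.add(rec.transcript_id)
            by_gene.setdefault(rec.gene_id, []).append(rec.transcript_id)
        object.__setattr__(self, "by_gene", by_gene)

    def __iter__(self) -> Iterator[CodingSequence]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, transcript_id: str) -> CodingSequence:
        for rec in self.records:
            if rec.transcript_id == transcript_id:
                return rec
        raise KeyError(transcript_id)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.by_gene)


class ValidationFlag(str, Enum):
    NOT_MULTIPLE_OF_3 = "NOT_MULTIPLE_OF_3"
    NO_START_ATG = "NO_START_ATG"
    INTERNAL_STOP = "INTERNAL_STOP"
    NO_TERMINAL_STOP = "NO_TERMINAL_STOP"
    AMBIGUOUS_BASES = "AMBIGUOUS_BASES"


@dataclass(frozen=True)
class ValidationReport:
    transcript_id: str
    flags: frozenset[ValidationFlag]
    n_ambiguous_codons: int

    @property
    def clean(self) -> bool:
        return not self.flags


# ---------------------------------------------------------------------------
# Header parsing
# ---------------------------------------------------------------------------

IdRule = Callable[[str], tuple[str, str]]

_ISOFORM_SUFFIX = re.compile(r"^(?P<gene>.+?)(?:-R[A-Z]\d*|-P[A-Z]\d*|\.\d+)$")
_GENE_ATTR = re.compile(r"\bgene[_=:]?(?:id)?[=:]\s*([^\s;|\]]+)", re.IGNORECASE)


def default_id_rule(header: str) -> tuple[str, str]:
    """Parse a FASTA header into (transcript_id, gene_id).

    The first whitespace token is the transcript id.  The gene id is taken
    from a ``gene=`` (or ``gene_id=``) attribute if one is present anywhere in
    the header; otherwise a trailing isoform suffix (``-RA``-style or a
    ``.N`` version) is stripped from the transcript id; otherwise the
    transcript id itself is used.
    """
    header = header.strip().lstrip(">")
    if not header:
        raise ValueError("empty FASTA header")
    transcript_id = header.split()[0]
    m = _GENE_ATTR.search(header)
    if m:
        return transcript_id, m.group(1)
    m = _ISOFORM_SUFFIX.match(transcript_id)
    if m:
        return transcript_id, m.group("gene")
    return transcript_id, transcript_id


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def read_cds_fasta(path: str | Path, id_rule: IdRule = default_id_rule) -> TranscriptCatalog:
    """Read a (possibly gzipped) multi-record CDS FASTA into a catalog.

    Record order is preserved; duplicate transcript ids and empty sequences
    are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[CodingSequence] = []
    with _open_text(path) as handle:
        head = handle.read(1)
        if head not in ("", ">"):
            raise ValueError(f"{path}: not a FASTA file (does not start with '>')")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            tid, gid = id_rule(rec.description)
            seq = str(rec.seq)
            if not seq:
                raise ValueError(f"{path}: empty sequence for record {tid}")
            records.append(CodingSequence(tid, gid, seq))
    return TranscriptCatalog(tuple(records))


def write_cds_fasta(catalog: TranscriptCatalog, path: str | Path, width: int = 60) -> None:
    """Write a catalog back to FASTA (``>transcript_id gene=gene_id``)."""
    with _open_text(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(
            SeqRecord(Seq(rec.seq), id=rec.transcript_id, description=f"gene={rec.gene_id}")
            for rec in catalog
        )


def validate_cds(
    cds: CodingSequence, require_start: bool = True, require_stop: bool = True
) -> ValidationReport:
    """Advisory frame/start/stop/ambiguity check for one CDS.

    INTERNAL_STOP means a stop triplet strictly before the final complete
    codon.  ``require_start`` / ``require_stop`` control whether the absence
    of ATG at position 1 or of a terminal stop is flagged at all.
    """
    flags: set[ValidationFlag] = set()
    seq = cds.seq
    if len(seq) % 3 != 0:
        flags.add(ValidationFlag.NOT_MULTIPLE_OF_3)
    if require_start and seq[:3] != "ATG":
        flags.add(ValidationFlag.NO_START_ATG)
    idx = codon_index_array(seq)
    n_ambiguous = int((idx < 0).sum())
    if any(b not in "ACGT" for b in seq):
        flags.add(ValidationFlag.AMBIGUOUS_BASES)
    if len(idx) > 1 and any(int(i) in _STOP_IDX for i in idx[:-1]):
        flags.add(ValidationFlag.INTERNAL_STOP)
    if require_stop and (len(idx) == 0 or int(idx[-1]) not in _STOP_IDX):
        flags.add(ValidationFlag.NO_TERMINAL_STOP)
    return ValidationReport(cds.transcript_id, frozenset(flags), n_ambiguous)


def select_longest_isoform(catalog: TranscriptCatalog) -> TranscriptCatalog:
    """Keep exactly one transcript per gene: the longest CDS, with equal
    lengths resolved by lexicographically smallest transcript id.

    Output order follows the first occurrence of each gene in the input, so
    the operation is deterministic and idempotent.
    """
    if len(catalog) == 0:
        raise ValueError("cannot select isoforms from an empty catalog")
    best: dict[str, CodingSequence] = {}
    order: list[str] = []
    for rec in catalog:
        cur = best.get(rec.gene_id)
        if cur is None:
            best[rec.gene_id] = rec
            order.append(rec.gene_id)
        elif rec.length_nt > cur.length_nt or (
            rec.length_nt == cur.length_nt and rec.transcript_id < cur.transcript_id
        ):
            # longer wins; on equal length the smaller transcript_id wins
            best[rec.gene_id] = rec
    return TranscriptCatalog(tuple(best[g] for g in order))


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line gene list; blank lines and '#' comments are
    ignored and duplicates collapse."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: set[str] = set()
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line)
    return genes
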