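"""Transcriptome FASTA ingestion, assembly statistics and read-retention arithmetic.

Assembled transcriptomes (Trinity-style) come as multi-FASTA files in which
each record id encodes a *component* — the assembler's gene-level grouping of
isoforms.  This module models those records, computes the usual assembly
summary statistics (N50, GC content, component counts) and the per-library
read-retention percentages reported for RNA-seq preprocessing.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptRecord",
    "TranscriptSet",
    "RetentionRecord",
    "AssemblyStats",
    "RetentionSummary",
    "normalize_sequence",
    "parse_component_id",
    "read_fasta",
    "write_fasta",
    "assembly_stats",
    "percent_clean",
    "summarize_retention",
    "read_retention_table",
]

# Trinity dialects: modern "TRINITY_DN100_c0_g1_i1" and legacy "comp17_c0_seq3".
_ISOFORM_SUFFIX = re.compile(r"_(?:i|seq)\d+$")

# Alphabetic IUPAC nucleotide codes; ambiguity codes collapse to N.
_NORMALIZE = {c: c for c in "ACGTN"}
_NORMALIZE["U"] = "T"
for _amb in "RYSWKMBDHV":
    _NORMALIZE[_amb] = "N"
_TRANSLATE = str.maketrans(
    {c: _NORMALIZE.get(c.upper()) for c in "ACGTUNRYSWKMBDHVacgtunryswkmbdhv"}
)

_VALID = set("ACGTN")


def normalize_sequence(raw: str, record_id: str = "<sequence>") -> str:
    """Map a raw nucleotide string onto the closed alphabet {A,C,G,T,N}.

    Lowercase is uppercased, U becomes T, IUPAC ambiguity codes become N.
    Any non-alphabetic residue is an error naming the record and position.
    """
    seq = raw.translate(_TRANSLATE)
    bad = set(seq) - _VALID
    if bad:
        for pos, ch in enumerate(seq):
            if ch not in _VALID:
                raise ValueError(
                    f"illegal residue {raw[pos]!r} in record {record_id!r} "
                    f"at position {pos}"
                )
    return seq


def parse_component_id(transcript_id: str) -> str:
    """Return the component (gene-level) key of a transcript id.

    Trinity isoform suffixes ``_i<N>`` and ``_seq<N>`` are stripped; any other
    id is its own component.
    """
    if not transcript_id:
        raise ValueError("empty transcript id")
    return _ISOFORM_SUFFIX.sub("", transcript_id)


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript with its component (gene) grouping."""

    id: str
    sequence: str
    component_id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty transcript id")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if not self.component_id:
            object.__setattr__(self, "component_id", parse_component_id(self.id))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptSet:
    """One strain's assembled transcripts."""

    strain: str
    records: list[TranscriptRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate transcript id {dup!r} in strain {self.strain!r}")

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    @property
    def component_ids(self) -> set[str]:
        return {r.component_id for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class RetentionRecord:
    """Raw versus retained read-pair counts for one sequencing library."""

    strain: str
    raw_pairs: int
    clean_pairs: int

    def __post_init__(self) -> None:
        if self.raw_pairs <= 0:
            raise ValueError(f"strain {self.strain!r}: raw_pairs must be > 0")
        if not 0 <= self.clean_pairs <= self.raw_pairs:
            raise ValueError(
                f"strain {self.strain!r}: need 0 <= clean_pairs <= raw_pairs"
            )


@dataclass(frozen=True)
class AssemblyStats:
    n_transcripts: int
    n_components: int
    total_bases: int
    gc_content: float
    n50: int


@dataclass(frozen=True)
class RetentionSummary:
    mean: float
    median: float
    min: float
    max: float


def read_fasta(path: str | Path, strain: str) -> TranscriptSet:
    """Read a transcriptome FASTA into a :class:`TranscriptSet`.

    Headers are kept up to the first whitespace as ids; sequences are
    normalized onto {A,C,G,T,N}.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(TranscriptRecord(id=rec.id, sequence=normalize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return TranscriptSet(strain=strain, records=records)


def write_fasta(ts: TranscriptSet, path: str | Path, width: int = 60) -> None:
    """Write a TranscriptSet as wrapped multi-FASTA."""
    with open(path, "w") as fh:
        for r in ts.records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def _n50(lengths: Iterable[int]) -> int:
    # Smallest length N such that contigs of length >= N hold at least half
    # of the assembly's bases: descending cumulative sum, real-valued half.
    lens = sorted(lengths, reverse=True)
    total = sum(lens)
    acc = 0
    for length in lens:
        acc += length
        if acc >= total / 2:
            return length
    raise AssertionError("unreachable: cumulative sum must reach total/2")


def assembly_stats(ts: TranscriptSet) -> AssemblyStats:
    """N50, GC content and transcript/component counts of one assembly.

    GC content is (#G + #C)/(#A + #C + #G + #T); N positions are excluded
    from both numerator and denominator.
    """
    if not ts.records:
        raise ValueError("empty TranscriptSet")
    gc = 0
    acgt = 0
    for r in ts.records:
        s = r.sequence
        gc += s.count("G") + s.count("C")
        acgt += len(s) - s.count("N")
    if acgt == 0:
        raise ValueError("GC content undefined: no non-N bases")
    return AssemblyStats(
        n_transcripts=len(ts.records),
        n_components=len(ts.component_ids),
        total_bases=ts.total_length,
        gc_content=gc / acgt,
        n50=_n50(len(r) for r in ts.records),
    )


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percent_clean(r: RetentionRecord) -> float:
    """Percentage of read pairs retained after preprocessing, half-up to 2 dp."""
    if r.raw_pairs <= 0:
        raise ValueError("raw_pairs must be > 0")
    return _round2(100.0 * r.clean_pairs / r.raw_pairs)


def summarize_retention(records: Iterable[RetentionRecord]) -> RetentionSummary:
    """Mean/median/min/max of per-strain retention percentages (2 dp each)."""
    percents = [percent_clean(r) for r in records]
    if not percents:
        raise ValueError("no retention records")
    return RetentionSummary(
        mean=_round2(statistics.mean(percents)),
        median=_round2(statistics.median(percents)),
        min=min(percents),
        max=max(percents),
    )


def read_retention_table(path: str | Path) -> list[RetentionRecord]:
    """Read a TSV with header ``strain\traw_pairs\tclean_pairs``."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["strain", "raw_pairs", "clean_pairs"]:
            raise ValueError(f"unexpected retention-table header: {header}")
        for line in fh:
            if not line.strip():
                continue
            strain, raw, clean = line.rstrip("\n").split("\t")
            records.append(RetentionRecord(strain, int(raw), int(clean)))
    return records
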