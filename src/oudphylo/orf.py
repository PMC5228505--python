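"""Six-frame ORF extraction and longest-ORF-per-component selection.

The coding-sequence input modes of the signature pipeline use one CDS per
gene: the longest open reading frame over all isoforms of a component.  ORFs
are stop-to-stop maximal codon runs (open ends allowed at sequence
boundaries), mirroring TransDecoder's LongOrfs step; an ATG anchor can be
required optionally.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .seqio import TranscriptRecord, TranscriptSet

__all__ = ["OrfRecord", "STOP_CODONS", "find_orfs", "longest_orf_per_component"]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_MIN_LEN_NT = 300  # 100 codons, the conventional LongOrfs threshold


@dataclass(frozen=True)
class OrfRecord:
    """One open reading frame.

    ``frame`` is +1/+2/+3 on the given strand and -1/-2/-3 on the reverse
    complement; ``start``/``end`` are 0-based half-open offsets on the
    reported strand (i.e. on the reverse complement for negative frames).
    ``cds_sequence`` spans the stop-free codon run plus its terminal stop
    codon when one is present within the sequence.
    """

    source_transcript_id: str
    component_id: str
    frame: int
    start: int
    end: int
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.cds_sequence):
            raise ValueError("ORF span does not match CDS length")
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")

    def __len__(self) -> int:
        return len(self.cds_sequence)


def _codon_runs(seq: str, offset: int) -> list[tuple[int, int]]:
    """Maximal stop-free codon runs of ``seq`` starting at frame ``offset``.

    Returns half-open nt spans on ``seq``; a run's span includes the stop
    codon that terminates it (if any).  Codons containing N cannot be called
    and break a run like a stop, but are not included in the span.
    """
    runs: list[tuple[int, int]] = []
    run_start: int | None = None
    pos = offset
    n = len(seq)
    while pos + 3 <= n:
        codon = seq[pos : pos + 3]
        if "N" in codon:
            if run_start is not None:
                runs.append((run_start, pos))
                run_start = None
        elif codon in STOP_CODONS:
            if run_start is not None:
                # terminal stop belongs to the run's span
                runs.append((run_start, pos + 3))
                run_start = None
        elif run_start is None:
            run_start = pos
        pos += 3
    if run_start is not None:
        runs.append((run_start, pos))
    return [(s, e) for s, e in runs if e > s]


def find_orfs(
    sequence: str,
    min_len_nt: int = DEFAULT_MIN_LEN_NT,
    *,
    require_start: bool = False,
    transcript_id: str = "<seq>",
    component_id: str | None = None,
) -> list[OrfRecord]:
    """All six-frame ORFs of length >= ``min_len_nt``.

    With ``require_start`` each run is trimmed to its first in-frame ATG
    (runs without one are dropped).
    """
    if min_len_nt < 3 or min_len_nt % 3 != 0:
        raise ValueError("min_len_nt must be >= 3 and divisible by 3")
    if component_id is None:
        component_id = transcript_id
    orfs: list[OrfRecord] = []
    rc = str(Seq(sequence).reverse_complement())
    for strand_seq, sign in ((sequence, 1), (rc, -1)):
        for offset in range(3):
            for start, end in _codon_runs(strand_seq, offset):
                cds = strand_seq[start:end]
                if require_start:
                    atg = _first_atg(cds)
                    if atg is None:
                        continue
                    start, cds = start + atg, cds[atg:]
                if len(cds) < min_len_nt:
                    continue
                orfs.append(
                    OrfRecord(
                        source_transcript_id=transcript_id,
                        component_id=component_id,
                        frame=sign * (offset + 1),
                        start=start,
                        end=start + len(cds),
                        cds_sequence=cds,
                    )
                )
    return orfs


def _first_atg(cds: str) -> int | None:
    for i in range(0, len(cds), 3):
        if cds[i : i + 3] == "ATG":
            return i
    return None


def _orf_sort_key(o: OrfRecord) -> tuple:
    # longest first; ties: forward strand, lower frame number, leftmost
    # start, then source id for cross-isoform determinism
    return (-len(o), o.frame < 0, abs(o.frame), o.start, o.source_transcript_id)


def longest_orf_per_component(
    ts: TranscriptSet,
    min_len_nt: int = DEFAULT_MIN_LEN_NT,
    *,
    require_start: bool = False,
) -> TranscriptSet:
    """Reduce a transcriptome to one CDS per component: its longest ORF.

    Output record ids are the component ids; components with no qualifying
    ORF are absent.
    """
    best: dict[str, OrfRecord] = {}
    for rec in ts.records:
        for orf in find_orfs(
            rec.sequence,
            min_len_nt,
            require_start=require_start,
            transcript_id=rec.id,
            component_id=rec.component_id,
        ):
            incumbent = best.get(orf.component_id)
            if incumbent is None or _orf_sort_key(orf) < _orf_sort_key(incumbent):
                best[orf.component_id] = orf
    records = [
        TranscriptRecord(id=cid, sequence=best[cid].cds_sequence, component_id=cid)
        for cid in sorted(best)
    ]
    return TranscriptSet(strain=ts.strain, records=records)
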