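"""k-mer counting and oligonucleotide usage deviation (OUD) signatures.

A transcriptome of total length L is summarized by the vector

    OUD(z) = (N(z) - E1(z)) / E0(z)        over all 4^k k-mers z,

where N(z) is the observed count of z over all transcripts, E0(z) =
(L - k)/4^k is the expectation under a uniform k-mer null, and E1(z) is the
expectation under an i.i.d. mononucleotide null, E1(z) = (L - k) * prod_j
p(z_j) with p the pooled mononucleotide frequencies.  A first-order Markov
null based on pooled dinucleotide transitions is available as an alternative
to E1.

The (L - k) window factor is used for both expectations, matching the
definition stated per transcriptome; the true number of counted windows
(which loses k-1 windows per transcript and skips windows containing N) is
recorded on :class:`KmerCounts` for diagnostics.

k-mers are indexed lexicographically with A < C < G < T, so index(z) is the
base-4 integer with digits A=0, C=1, G=2, T=3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Literal

import numpy as np

from .seqio import TranscriptSet

__all__ = [
    "KmerCounts",
    "OUDSignature",
    "kmer_to_index",
    "index_to_kmer",
    "all_kmers",
    "count_kmers",
    "expected_uniform",
    "expected_iid",
    "expected_markov1",
    "oud",
]

_BASE_ORDER = "ACGT"
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASE_ORDER):
    _CODE[ord(_b)] = _i

StrandPolicy = Literal["forward", "canonical"]
NullModel = Literal["iid", "markov1"]


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for ch in kmer:
        code = _CODE[ord(ch)]
        if code < 0:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer {kmer!r}")
        idx = idx * 4 + int(code)
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    chars = []
    for _ in range(k):
        idx, rem = divmod(idx, 4)
        chars.append(_BASE_ORDER[rem])
    return "".join(reversed(chars))


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic (index) order."""
    return ["".join(p) for p in product(_BASE_ORDER, repeat=k)]


def _revcomp_index_map(k: int) -> np.ndarray:
    """idx -> index of the reverse complement k-mer."""
    n = 4 ** k
    idx = np.arange(n, dtype=np.int64)
    rc = np.zeros(n, dtype=np.int64)
    rem = idx.copy()
    for _ in range(k):
        rem, digit = np.divmod(rem, 4)
        rc = rc * 4 + (3 - digit)  # complement: A<->T (0<->3), C<->G (1<->2)
    return rc


@dataclass
class KmerCounts:
    """Observed k-mer counts of one transcriptome.

    ``counts`` is indexed lexicographically (AA..A first).  ``L`` is the
    total transcriptome length in bases (N included), ``n_windows`` the
    number of valid windows actually counted, ``mono`` the pooled
    mononucleotide counts over {A,C,G,T} and ``dinuc`` the pooled 4x4
    adjacent-pair counts (first base -> row).
    """

    k: int
    counts: np.ndarray
    n_windows: int
    L: int
    mono: np.ndarray
    dinuc: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.shape != (4 ** self.k,):
            raise ValueError("counts must have length 4^k")
        if int(self.counts.sum()) != self.n_windows:
            raise ValueError("counts must sum to n_windows")


@dataclass
class OUDSignature:
    """Normalized k-mer usage deviation vector of one strain."""

    k: int
    values: np.ndarray
    null_model: str = "iid"
    strain: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4 ** self.k,):
            raise ValueError(f"signature must have length 4^{self.k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signature values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path) -> None:
        kmers = all_kmers(self.k)
        with open(path, "w") as fh:
            fh.write("kmer\toud_value\n")
            for km, v in zip(kmers, self.values):
                fh.write(f"{km}\t{v!r}\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "strain": self.strain,
            "null_model": self.null_model,
            "values": [float(v) for v in self.values],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "OUDSignature":
        payload = json.loads(Path(path).read_text())
        return cls(
            k=payload["k"],
            values=np.array(payload["values"], dtype=float),
            null_model=payload["null_model"],
            strain=payload.get("strain", ""),
        )


def _encode(sequence: str) -> np.ndarray:
    """Base codes A,C,G,T -> 0..3; N (or anything else) -> -1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def count_kmers(
    ts: TranscriptSet, k: int, strand_policy: StrandPolicy = "forward"
) -> KmerCounts:
    """Count all length-k windows of every transcript.

    Windows never span transcript boundaries; windows containing N are
    skipped.  Under the canonical policy each window increments the
    lexicographically smaller of the window and its reverse complement.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if strand_policy not in ("forward", "canonical"):
        raise ValueError(f"unknown strand policy {strand_policy!r}")
    n = 4 ** k
    counts = np.zeros(n, dtype=np.int64)
    mono = np.zeros(4, dtype=np.int64)
    dinuc = np.zeros((4, 4), dtype=np.int64)
    rc_map = _revcomp_index_map(k) if strand_policy == "canonical" else None
    total_windows = 0
    any_countable = False
    for rec in ts.records:
        codes = _encode(rec.sequence)
        valid = codes >= 0
        mono += np.bincount(codes[valid], minlength=4)
        if len(codes) >= 2:
            both = valid[:-1] & valid[1:]
            pair = codes[:-1][both] * 4 + codes[1:][both]
            dinuc += np.bincount(pair, minlength=16).reshape(4, 4)
        w = len(codes) - k + 1
        if w <= 0:
            continue
        any_countable = True
        acc = np.zeros(w, dtype=np.int64)
        bad = np.zeros(w, dtype=bool)
        for j in range(k):
            acc = acc * 4 + np.where(valid[j : j + w], codes[j : j + w], 0)
            bad |= ~valid[j : j + w]
        window_idx = acc[~bad]
        if rc_map is not None:
            window_idx = np.minimum(window_idx, rc_map[window_idx])
        counts += np.bincount(window_idx, minlength=n)
        total_windows += len(window_idx)
    if not any_countable:
        raise ValueError("no countable windows: no transcript of length >= k")
    return KmerCounts(
        k=k, counts=counts, n_windows=total_windows, L=ts.total_length,
        mono=mono, dinuc=dinuc,
    )


def expected_uniform(L: int, k: int) -> np.ndarray:
    """E0(z) = (L - k)/4^k for every z: the uniform-usage expectation."""
    if L <= k:
        raise ValueError(f"L={L} must exceed k={k}: uniform expectation undefined")
    return np.full(4 ** k, (L - k) / 4 ** k, dtype=float)


def expected_iid(counts: KmerCounts) -> np.ndarray:
    """E1(z) = (L - k) * prod_j p(z_j), p from pooled mononucleotide counts.

    Uses the same (L - k) window factor as the uniform expectation, so a
    perfectly uniform composition gives E1 = E0 exactly.
    """
    total = counts.mono.sum()
    if total <= 0:
        raise ValueError("no mononucleotide counts")
    if counts.L <= counts.k:
        raise ValueError("L must exceed k")
    p = counts.mono / total
    e = p.copy()
    for _ in range(counts.k - 1):
        e = np.outer(e, p).ravel()
    return (counts.L - counts.k) * e


def expected_markov1(counts: KmerCounts) -> np.ndarray:
    """First-order Markov expectation from pooled dinucleotide transitions.

    E(z) = (L - k) * p(z_1) * prod_{j>=2} p(z_j | z_{j-1}).  When the
    composition is exactly i.i.d. this reduces to the mononucleotide
    expectation.
    """
    if counts.k < 2:
        raise ValueError("markov1 expectation requires k >= 2")
    if counts.dinuc is None:
        raise ValueError("dinucleotide counts unavailable")
    if np.any(counts.mono == 0):
        raise ValueError("zero-count conditioning base: markov1 undefined")
    row_sums = counts.dinuc.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("zero-count conditioning base: markov1 undefined")
    trans = counts.dinuc / row_sums[:, None]
    p1 = counts.mono / counts.mono.sum()
    e = p1.copy()
    for _ in range(counts.k - 1):
        last = np.arange(len(e)) % 4
        e = (e[:, None] * trans[last]).ravel()
    return (counts.L - counts.k) * e


def oud(
    counts: KmerCounts, null: NullModel = "iid", strain: str = ""
) -> OUDSignature:
    """The OUD signature (N - E_null) / E0 of one transcriptome."""
    e0 = expected_uniform(counts.L, counts.k)
    if null == "iid":
        e_null = expected_iid(counts)
    elif null == "markov1":
        e_null = expected_markov1(counts)
    else:
        raise ValueError(f"unknown null model {null!r}")
    values = (counts.counts - e_null) / e0
    return OUDSignature(k=counts.k, values=values, null_model=null, strain=strain)


def signature_from_transcripts(
    ts: TranscriptSet,
    k: int,
    null: NullModel = "iid",
    strand_policy: StrandPolicy = "forward",
) -> OUDSignature:
    """Convenience: count k-mers and compute the OUD signature in one call."""
    return oud(count_kmers(ts, k, strand_policy), null=null, strain=ts.strain)
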