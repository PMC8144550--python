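"""FASTQ input and minimal preprocessing: mean-quality filtering and
overlap-merging of read pairs.

The merger is deliberately simple: best ungapped 3' overlap between R1 and
the reverse-complement of R2, with a quality-weighted consensus at
disagreeing overlap columns. Adapter trimming is out of scope; amplicon
reads are primer-delimited and the demultiplexer tolerates short extraneous
prefixes through edit-distance matching. Pre-merged single-end FASTQ is
accepted as-is (filtering only).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterator, Sequence, Union

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqError
from .panel import Read, revcomp


@dataclass
class PreprocessParams:
    min_mean_q: float = 30.0          # drop reads with mean Phred below this
    min_overlap: int = 10             # minimum R1/R2 overlap length (nt)
    max_overlap_mismatch: float = 0.2  # max mismatch fraction in the overlap


@dataclass
class PreprocessStats:
    """Read accounting; ``input == emitted + dropped_quality + unmergeable``."""

    input: int = 0
    emitted: int = 0
    dropped_quality: int = 0
    unmergeable: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _open_text(path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path) -> Iterator[Read]:
    """Iterate FASTQ records (plain or gzip). Raises FastqError with the
    record index on truncated/malformed input."""
    count = 0
    try:
        with _open_text(path) as handle:
            for title, seq, qual in FastqGeneralIterator(handle):
                count += 1
                yield Read(read_id=title.split()[0], sequence=seq.upper(), qualities=qual)
    except ValueError as exc:
        raise FastqError(f"{path}: malformed FASTQ near record {count + 1}: {exc}") from exc


def write_fastq(reads: Sequence[Read], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for r in reads:
            qual = r.qualities if r.qualities is not None else "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def mean_quality(read: Read) -> float:
    if not read.qualities:
        return float("inf")  # no qualities: nothing to filter on
    arr = np.frombuffer(read.qualities.encode("ascii"), dtype=np.uint8)
    return float(arr.mean()) - 33.0


def merge_pair(r1: Read, r2: Read, params: PreprocessParams) -> Read | None:
    """Merge a pair by best ungapped overlap of R1 with revcomp(R2).

    Returns the merged read, or None when no acceptable overlap exists.
    Disagreeing overlap columns take the base with the higher Phred score.
    """
    s1 = r1.sequence
    s2 = revcomp(r2.sequence)
    q1 = r1.qualities or "I" * len(s1)
    q2 = (r2.qualities or "I" * len(r2.sequence))[::-1]
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    max_o = min(len(s1), len(s2))
    if max_o < params.min_overlap:
        return None

    best = None  # (mismatch_fraction, -overlap)
    for o in range(params.min_overlap, max_o + 1):
        mism = int(np.count_nonzero(a1[len(s1) - o:] != a2[:o]))
        frac = mism / o
        if frac <= params.max_overlap_mismatch:
            key = (frac, -o)
            if best is None or key < best[0]:
                best = (key, o, mism)
    if best is None:
        return None
    _, o, mism = best

    head = s1[: len(s1) - o]
    tail = s2[o:]
    head_q = q1[: len(s1) - o]
    tail_q = q2[o:]
    if mism == 0:
        ov = s1[len(s1) - o:]
        ov_q = "".join(
            max(c1, c2) for c1, c2 in zip(q1[len(s1) - o:], q2[:o])
        )
    else:
        ov_chars = []
        ov_quals = []
        for c1, c2, p1, p2 in zip(s1[len(s1) - o:], s2[:o], q1[len(s1) - o:], q2[:o]):
            if c1 == c2:
                ov_chars.append(c1)
                ov_quals.append(max(p1, p2))
            elif p1 >= p2:
                ov_chars.append(c1)
                ov_quals.append(p1)
            else:
                ov_chars.append(c2)
                ov_quals.append(p2)
        ov = "".join(ov_chars)
        ov_q = "".join(ov_quals)
    return Read(read_id=r1.read_id, sequence=head + ov + tail, qualities=head_q + ov_q + tail_q)


def preprocess_sample(
    r1_path,
    r2_path=None,
    params: PreprocessParams | None = None,
) -> tuple[list[Read], PreprocessStats]:
    """Filter (and merge, when R2 is given) one sample's FASTQ input."""
    params = params or PreprocessParams()
    stats = PreprocessStats()
    out: list[Read] = []
    if r2_path is None:
        for read in read_fastq(r1_path):
            stats.input += 1
            if mean_quality(read) < params.min_mean_q:
                stats.dropped_quality += 1
            else:
                out.append(read)
                stats.emitted += 1
        return out, stats

    reads1 = list(read_fastq(r1_path))
    reads2 = list(read_fastq(r2_path))
    if len(reads1) != len(reads2):
        raise FastqError(
            f"R1/R2 record count mismatch: {len(reads1)} vs {len(reads2)}"
        )
    for r1, r2 in zip(reads1, reads2):
        stats.input += 1
        merged = merge_pair(r1, r2, params)
        if merged is None:
            stats.unmergeable += 1
            continue
        if mean_quality(merged) < params.min_mean_q:
            stats.dropped_quality += 1
            continue
        out.append(merged)
        stats.emitted += 1
    return out, stats


def preprocess_reads(
    tx_r1,
    tx_r2=None,
    m_r1=None,
    m_r2=None,
    params: PreprocessParams | None = None,
) -> tuple[list[Read], list[Read], dict]:
    """Preprocess treatment and mock samples; returns (tx_reads, m_reads, stats)."""
    tx_reads, tx_stats = preprocess_sample(tx_r1, tx_r2, params)
    m_reads, m_stats = preprocess_sample(m_r1, m_r2, params)
    return tx_reads, m_reads, {"tx": tx_stats.as_dict(), "mock": m_stats.as_dict()}
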