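"""Primer-based demultiplexing of merged reads to panel loci.

Each read's prefix is matched against every primer (forward and reverse of
every site) by minimum Levenshtein distance, and the assignment is verified
by matching the read's 3' end against a partner primer. Reads whose two ends
match primers of the *same* site are assigned to that locus; reads whose
ends match primers of *different* sites are putative fusion amplicons and go
to the translocation-candidate pool; everything else is discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from .panel import Read, SiteConfig, revcomp


@dataclass(frozen=True)
class Primer:
    primer_id: str
    site_id: str
    end: str  # "F" (forward) or "R" (reverse)
    sequence: str


@dataclass
class DemuxParams:
    #: maximum edit distance for a primer match; None -> floor(len/4) per primer
    max_primer_dist: int | None = None
    #: extra target length beyond the primer length when scanning a read end
    prefix_slack: int = 4

    def dist_cap(self, primer_len: int) -> int:
        if self.max_primer_dist is not None:
            return self.max_primer_dist
        return primer_len // 4


@dataclass
class Assignment:
    read_ref: str
    site_id: str | None
    orientation: str | None  # "forward" | "reverse-complement"
    status: str  # "assigned" | "candidate" | "discarded"
    prefix_primer: str | None = None
    suffix_primer: str | None = None
    reason: str | None = None  # for discarded reads


def build_primer_set(panel: Sequence[SiteConfig]) -> list[Primer]:
    primers = []
    for site in panel:
        primers.append(Primer(f"{site.site_id}:F", site.site_id, "F", site.fwd_primer))
        primers.append(Primer(f"{site.site_id}:R", site.site_id, "R", site.rev_primer))
    return primers


def match_primer(
    segment: str,
    primer_set: Sequence[tuple[str, str] | Primer],
    slack: int = 4,
) -> tuple[str, int, bool]:
    """Best primer for the 5' end of ``segment`` by Levenshtein distance.

    For each primer the segment window is the primer length plus ``slack``;
    edlib's prefix mode takes the best-scoring window implicitly. Returns
    ``(primer_id, distance, unique)``; ``unique`` is False when two or more
    primers tie at the minimum.
    """
    best_id, best_dist, ties = None, math.inf, 0
    for primer in primer_set:
        pid, seq = (primer.primer_id, primer.sequence) if isinstance(primer, Primer) else primer
        target = segment[: len(seq) + slack]
        dist = edlib.align(seq, target, mode="SHW", task="distance")["editDistance"]
        if dist < best_dist:
            best_id, best_dist, ties = pid, dist, 1
        elif dist == best_dist:
            ties += 1
    return best_id, int(best_dist), ties == 1


def _best_end_match(segment: str, primers: Sequence[Primer], slack: int):
    """(Primer, dist, unique) for the best primer at the segment's 5' end."""
    best, best_dist, ties = None, math.inf, 0
    for primer in primers:
        target = segment[: len(primer.sequence) + slack]
        dist = edlib.align(primer.sequence, target, mode="SHW", task="distance")["editDistance"]
        if dist < best_dist:
            best, best_dist, ties = primer, dist, 1
        elif dist == best_dist:
            ties += 1
    return best, int(best_dist), ties == 1


def assign_read(
    read: Read | str,
    panel: Sequence[SiteConfig],
    params: DemuxParams | None = None,
    primers: Sequence[Primer] | None = None,
) -> Assignment:
    """Assign one read to a locus, a translocation-candidate pool, or discard.

    The read's 5' end and the 5' end of its reverse-complement (= the read's
    3' end, in primer orientation) are each matched against all primers. A
    same-site (F, R) pair within the distance cap is an assignment; a
    cross-site or same-end pair is a fusion candidate; anything else is
    discarded. Ambiguous (tied) primer matches are discarded as unsafe.
    """
    params = params or DemuxParams()
    primers = primers if primers is not None else build_primer_set(panel)
    if isinstance(read, Read):
        seq, rid = read.sequence.upper(), read.read_id
    else:
        seq, rid = read.upper(), ""
    rc = revcomp(seq)

    p5, d5, uniq5 = _best_end_match(seq, primers, params.prefix_slack)
    p3, d3, uniq3 = _best_end_match(rc, primers, params.prefix_slack)

    ok5 = p5 is not None and d5 <= params.dist_cap(len(p5.sequence))
    ok3 = p3 is not None and d3 <= params.dist_cap(len(p3.sequence))
    if not (ok5 and ok3):
        return Assignment(rid, None, None, "discarded", reason="no_primer_match")
    if not (uniq5 and uniq3):
        return Assignment(rid, None, None, "discarded", reason="ambiguous_primer")

    if p5.site_id == p3.site_id and {p5.end, p3.end} == {"F", "R"}:
        orientation = "forward" if p5.end == "F" else "reverse-complement"
        return Assignment(
            rid, p5.site_id, orientation, "assigned",
            prefix_primer=p5.primer_id, suffix_primer=p3.primer_id,
        )
    # Ends identified but inconsistent: putative fusion amplicon.
    return Assignment(
        rid, None, None, "candidate",
        prefix_primer=p5.primer_id, suffix_primer=p3.primer_id,
    )


@dataclass
class DemuxPools:
    """Partition of one sample's reads."""

    site_reads: dict[str, list[Read]]
    candidates: list[tuple[Read, Assignment]]
    discarded: int
    #: reads assigned per site, already flipped to forward amplicon orientation
    totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.totals:
            self.totals = {sid: len(rs) for sid, rs in self.site_reads.items()}

    @property
    def n_assigned(self) -> int:
        return sum(self.totals.values())


def build_pools(
    reads: Iterable[Read],
    panel: Sequence[SiteConfig],
    params: DemuxParams | None = None,
) -> DemuxPools:
    """Demultiplex a sample. Assigned reads are stored in forward amplicon
    orientation (reverse-complement reads are flipped), so downstream
    alignment sees one strand only. Assignment is cached per unique sequence
    since it depends on the sequence alone."""
    params = params or DemuxParams()
    primers = build_primer_set(panel)
    site_reads: dict[str, list[Read]] = {s.site_id: [] for s in panel}
    candidates: list[tuple[Read, Assignment]] = []
    discarded = 0
    cache: dict[str, Assignment] = {}
    for read in reads:
        seq = read.sequence.upper()
        asg = cache.get(seq)
        if asg is None:
            asg = assign_read(read, panel, params, primers)
            cache[seq] = asg
        if asg.status == "assigned":
            if asg.orientation == "reverse-complement":
                read = Read(read.read_id, revcomp(seq),
                            read.qualities[::-1] if read.qualities else None)
            site_reads[asg.site_id].append(read)
        elif asg.status == "candidate":
            candidates.append((read, Assignment(
                read.read_id, None, None, "candidate",
                prefix_primer=asg.prefix_primer, suffix_primer=asg.suffix_primer,
            )))
        else:
            discarded += 1
    return DemuxPools(site_reads=site_reads, candidates=candidates, discarded=discarded)
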