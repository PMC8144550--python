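"""Translocation (fusion-amplicon) detection between panel loci.

In a multiplex PCR every primer pair is present in one reaction, so a
genomic fusion of two cut loci yields a hybrid amplicon whose two ends
carry primers of *different* sites. The demultiplexer diverts such
mixed-primer reads to a candidate pool; here each candidate is typed into
one of four end-configuration rules, validated by alignment against the
putative fusion amplicon (the two loci joined bluntly at their expected
cut-sites), and each site pair is scored with a hypergeometric tail test
of the treatment candidate count against the pooled treatment + mock
candidates, with Benjamini-Hochberg FDR correction across pairs.

Rule taxonomy for a read r and sites a, b (F/R = forward/reverse primer):

1. r = F(a) + ... + revcomp(R(b))      (or its reverse-complement)
2. r = F(b) + ... + revcomp(R(a))      (rule 1 with roles swapped)
3. r = F(a) + ... + revcomp(F(b))      (head-to-head; two forward ends)
4. r = R(a) + ... + revcomp(R(b))      (tail-to-tail; two reverse ends)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .demux import Assignment
from .panel import CutSite, Read, SiteConfig, revcomp


@dataclass
class TranslocationParams:
    min_identity: float = 0.85   # alignment identity to the fusion amplicon
    min_coverage: float = 0.80   # read length / fusion amplicon length
    fdr_threshold: float = 0.05
    all_pairs: bool = False      # test every pair, not only active-site pairs


@dataclass(frozen=True)
class FusionCandidate:
    read_ref: str
    site_a: str
    site_b: str
    rule: int             # 1..4
    orientation: str      # "as-written" | "reverse-complement"
    sample: str           # "tx" | "mock"


@dataclass
class TranslocationResult:
    site_a: str
    site_b: str
    c_tx: int
    c_m: int
    n: int          # hypergeometric draw size (geometric mean of Tx totals)
    N: int          # population size (n + geometric mean of mock totals)
    p_value: float
    q_value: float = math.nan
    significant: bool = False


def type_candidate(
    read: Read,
    assignment: Assignment,
    sample: str,
) -> FusionCandidate | None:
    """Map a mixed-primer demultiplexing candidate to a fusion rule.

    The assignment carries the best prefix primer and the best primer of the
    reverse-complemented read (i.e. the read's 3' end). Same-site pairs are
    not fusions and return None.
    """
    if assignment.prefix_primer is None or assignment.suffix_primer is None:
        return None
    sa, end_a = assignment.prefix_primer.rsplit(":", 1)
    sb, end_b = assignment.suffix_primer.rsplit(":", 1)
    if sa == sb:
        return None
    ends = (end_a, end_b)
    if ends == ("F", "R"):
        rule, orientation, pair = 1, "as-written", (sa, sb)
    elif ends == ("R", "F"):
        # revcomp of F(sb) + ... + revcomp(R(sa))
        rule, orientation, pair = 1, "reverse-complement", (sb, sa)
    elif ends == ("F", "F"):
        rule, orientation, pair = 3, "as-written", (sa, sb)
    else:  # ("R", "R")
        rule, orientation, pair = 4, "as-written", (sa, sb)
    return FusionCandidate(
        read_ref=read.read_id, site_a=pair[0], site_b=pair[1],
        rule=rule, orientation=orientation, sample=sample,
    )


def build_fusion_amplicon(
    site_a: SiteConfig,
    site_b: SiteConfig,
    rule: int,
    cut_a: CutSite,
    cut_b: CutSite,
) -> str:
    """Putative fusion amplicon for a rule: the primer-to-cut segment of one
    locus joined bluntly at the cut indices to the cut-to-primer segment of
    the other, reverse-complementing segments as the rule requires."""
    if site_a.site_id == site_b.site_id:
        raise ValueError("fusion requires two distinct sites")
    A, B = site_a.amplicon, site_b.amplicon
    ca, cb = cut_a.index, cut_b.index
    if rule == 1:
        return A[: ca + 1] + B[cb + 1:]
    if rule == 2:
        return B[: cb + 1] + A[ca + 1:]
    if rule == 3:
        return A[: ca + 1] + revcomp(B[: cb + 1])
    if rule == 4:
        return revcomp(A[ca + 1:]) + B[cb + 1:]
    raise ValueError(f"unknown fusion rule {rule!r}")


def _candidate_matches(
    seq: str, fusion_amp: str, params: TranslocationParams
) -> bool:
    if len(seq) < params.min_coverage * len(fusion_amp):
        return False
    # Semi-global: the read must align end-to-end inside the fusion amplicon.
    dist = edlib.align(seq, fusion_amp, mode="HW", task="distance")["editDistance"]
    identity = 1.0 - dist / len(seq)
    return identity >= params.min_identity


def validate_candidates(
    candidates: Sequence[tuple[Read, FusionCandidate]],
    panel_map: Mapping[str, SiteConfig],
    cut_sites: Mapping[str, CutSite],
    params: TranslocationParams | None = None,
) -> dict[tuple[str, str], dict[str, int]]:
    """Align candidates to their putative fusion amplicons and count the
    retained reads per unordered site pair and sample."""
    params = params or TranslocationParams()
    counts: dict[tuple[str, str], dict[str, int]] = {}
    amp_cache: dict[tuple[str, str, int], str] = {}
    for read, cand in candidates:
        key = (cand.site_a, cand.site_b, cand.rule)
        fusion_amp = amp_cache.get(key)
        if fusion_amp is None:
            fusion_amp = build_fusion_amplicon(
                panel_map[cand.site_a], panel_map[cand.site_b], cand.rule,
                cut_sites[cand.site_a], cut_sites[cand.site_b],
            )
            amp_cache[key] = fusion_amp
        seq = read.sequence.upper()
        if cand.orientation == "reverse-complement":
            seq = revcomp(seq)
        if not _candidate_matches(seq, fusion_amp, params):
            continue
        pair = tuple(sorted((cand.site_a, cand.site_b)))
        bucket = counts.setdefault(pair, {"tx": 0, "mock": 0})
        bucket[cand.sample] += 1
    return counts


def hypergeometric_tail(b: int, N: int, B: int, n: int) -> float:
    """Upper-tail P(X >= b) for X ~ Hypergeometric(N, B, n), summed in log
    space for stability."""
    if not (0 <= b and 0 <= B <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds: b={b}, N={N}, B={B}, n={n}")
    upper = min(n, B)
    if b <= max(0, n + B - N):
        return 1.0
    if b > upper:
        return 0.0
    ks = np.arange(b, upper + 1)
    logs = hypergeom.logpmf(ks, N, B, n)
    return float(min(1.0, math.exp(logsumexp(logs))))


def test_pair(
    pair: tuple[str, str],
    c_tx: int,
    c_m: int,
    tx_totals: Mapping[str, int],
    m_totals: Mapping[str, int],
) -> TranslocationResult | None:
    """Hypergeometric test of one site pair's fusion-read counts.

    Draw and population sizes are the rounded geometric means of the two
    sites' per-sample read totals (symmetric in the pair). Pairs where a
    site has no reads are skipped.
    """
    a, b_site = pair
    if min(tx_totals.get(a, 0), tx_totals.get(b_site, 0)) == 0 or \
       min(m_totals.get(a, 0), m_totals.get(b_site, 0)) == 0:
        return None
    n = round(math.sqrt(tx_totals[a] * tx_totals[b_site]))
    N = n + round(math.sqrt(m_totals[a] * m_totals[b_site]))
    b = c_tx
    B = min(c_tx + c_m, N)  # clamp for degenerate small-depth cases
    b = min(b, B, n)
    p = hypergeometric_tail(b, N, B, n)
    return TranslocationResult(
        site_a=a, site_b=b_site, c_tx=c_tx, c_m=c_m, n=n, N=N, p_value=p,
    )


def fdr_correct(
    results: Sequence[TranslocationResult],
    threshold: float = 0.05,
) -> list[TranslocationResult]:
    """Benjamini-Hochberg adjustment across all tested pairs (in place)."""
    if not results:
        return []
    pvals = [r.p_value for r in results]
    reject, qvals, _, _ = multipletests(pvals, alpha=threshold, method="fdr_bh")
    for r, q, rej in zip(results, qvals, reject):
        r.q_value = float(q)
        r.significant = bool(q <= threshold)
    return list(results)


def analyze_translocations(
    tx_candidates: Sequence[tuple[Read, Assignment]],
    m_candidates: Sequence[tuple[Read, Assignment]],
    panel: Sequence[SiteConfig],
    cut_sites: Mapping[str, CutSite],
    tx_totals: Mapping[str, int],
    m_totals: Mapping[str, int],
    active_sites: set[str] | None = None,
    params: TranslocationParams | None = None,
) -> tuple[list[TranslocationResult], list[FusionCandidate]]:
    """Full translocation analysis from demultiplexing candidate pools.

    Only pairs whose two sites are active (editing at/above threshold) are
    tested unless ``params.all_pairs``; pairs without a single validated
    candidate in either sample are not tested at all.
    """
    params = params or TranslocationParams()
    panel_map = {s.site_id: s for s in panel}
    typed: list[tuple[Read, FusionCandidate]] = []
    evidence: list[FusionCandidate] = []
    for sample, pool in (("tx", tx_candidates), ("mock", m_candidates)):
        for read, assignment in pool:
            cand = type_candidate(read, assignment, sample)
            if cand is not None:
                typed.append((read, cand))
                evidence.append(cand)
    counts = validate_candidates(typed, panel_map, cut_sites, params)

    results = []
    for pair, c in sorted(counts.items()):
        if c["tx"] + c["mock"] < 1:
            continue
        if not params.all_pairs and active_sites is not None:
            if pair[0] not in active_sites or pair[1] not in active_sites:
                continue
        res = test_pair(pair, c["tx"], c["mock"], tx_totals, m_totals)
        if res is not None:
            results.append(res)
    return fdr_correct(results, params.fdr_threshold), evidence
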