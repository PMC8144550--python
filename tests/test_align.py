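import numpy as np
import pytest

from ampedit.align import (
    AlignParams,
    Alignment,
    EventTable,
    IndelCall,
    build_event_table,
    extract_indels,
    needleman_wunsch,
)
from ampedit.panel import CutSite, Read, locate_cut_site
from ampedit.simulate import apply_edit

from .oracles import affine_nw_score, enumerate_optimal_deletion_positions

REF = (
    "ACGTTGCAGGCCTTAAGGCCAACCGGTTACGTACGTAAGGTTCCAAGGTTCCGGAACCTT"
    "GGAACCTTGGCCAAGGCCAATTGGCCAATTGGAACCGGTTAACCGGAATTCCGG"
)


def test_identical_sequences_align_without_gaps():
    aln = needleman_wunsch(REF, REF, AlignParams(), cut_site=50)
    assert aln.ref_aln == aln.read_aln == REF
    assert aln.score == 5.0 * len(REF)
    assert extract_indels(aln, (0, len(REF) - 1)) == []


def test_single_deletion_called_once():
    read = REF[:50] + REF[53:]
    aln = needleman_wunsch(read, REF, AlignParams(), cut_site=50)
    calls = extract_indels(aln, (0, len(REF) - 1))
    assert len(calls) == 1
    assert calls[0].kind == "deletion" and calls[0].length == 3


def test_single_insertion_called_once():
    read = REF[:50] + "TTA" + REF[50:]
    aln = needleman_wunsch(read, REF, AlignParams(), cut_site=50)
    calls = extract_indels(aln, (0, len(REF) - 1))
    assert len(calls) == 1
    assert calls[0].kind == "insertion" and calls[0].length == 3


@pytest.mark.parametrize("cut", [5, 7, 9, 11])
def test_homopolymer_deletion_placed_nearest_cut(cut):
    """Among co-optimal placements of a 1-bp deletion in a homopolymer, the
    reported position is the one closest to the cut-site — checked against
    exhaustive enumeration of all optimal traceback paths."""
    ref = "GGTTCC" + "AAAAA" + "CCGGTT"  # A-run at reference 6..10
    read = "GGTTCC" + "AAAA" + "CCGGTT"
    aln = needleman_wunsch(read, ref, AlignParams(), cut_site=cut)
    (call,) = extract_indels(aln, (0, len(ref) - 1))
    candidates = enumerate_optimal_deletion_positions(read, ref)
    assert call.position in candidates
    best = min(abs(p - cut) for p in candidates)
    assert abs(call.position - cut) == best


def test_score_matches_plain_dp_oracle():
    """Tie-broken traceback never changes the optimal DP score (random
    instances up to 50 nt against an independent plain implementation)."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    for _ in range(25):
        m = int(rng.integers(10, 50))
        ref = "".join(rng.choice(bases, m))
        read = list(ref)
        for _ in range(int(rng.integers(0, 4))):
            op = rng.integers(0, 3)
            pos = int(rng.integers(0, len(read)))
            if op == 0 and len(read) > 2:
                del read[pos]
            elif op == 1:
                read.insert(pos, str(rng.choice(bases)))
            else:
                read[pos] = str(rng.choice(bases))
        read = "".join(read)
        aln = needleman_wunsch(read, ref, AlignParams(), cut_site=m // 2)
        assert aln.score == affine_nw_score(read, ref)
        # alignment strings spell the input sequences
        assert aln.ref_aln.replace("-", "") == ref
        assert aln.read_aln.replace("-", "") == read


def test_extract_indels_window_filtering():
    aln = Alignment(
        ref_aln="A" * 100 + "CG" + "A" * 18,
        read_aln="A" * 100 + "--" + "A" * 18,
        score=0.0,
    )
    assert extract_indels(aln, (95, 115)) == [IndelCall("deletion", 2, 100)]
    assert extract_indels(aln, (10, 30)) == []


def test_extract_indels_separate_gaps():
    ref = "ACGTACGTACGT"
    read = "ACG-ACG-ACGT".replace("-", "")
    aln = needleman_wunsch(read, ref, AlignParams(match=5, mismatch=-4, gap_open=-6, gap_extend=-1))
    calls = extract_indels(aln, (0, len(ref) - 1))
    assert sorted(c.length for c in calls) == [1, 1]
    assert all(c.kind == "deletion" for c in calls)


def _mk_reads(seqs, prefix):
    return [Read(f"{prefix}{k}", s) for k, s in enumerate(seqs)]


def test_event_table_counts_basic(tiny_site):
    cut = locate_cut_site(tiny_site)
    edited = apply_edit(tiny_site.amplicon, cut, "deletion", 1)
    tx = _mk_reads([edited] * 10, "tx")
    m = _mk_reads([tiny_site.amplicon] * 10, "m")
    table = build_event_table(tx, m, tiny_site, cut)
    assert table.n_tx == 10 and table.n_m == 10
    assert table.counts[("deletion", 1, cut.index)] == [10, 0]
    assert len(table.tx_read_cells) == 10


def test_event_table_multi_event_read(panel2):
    site = panel2[0]
    cut = locate_cut_site(site)
    seq = site.amplicon
    # one deletion at the cut plus one insertion 3 bp downstream
    edited = apply_edit(seq, cut, "deletion", 1)
    edited = edited[: cut.index + 3] + "GT" + edited[cut.index + 3:]
    table = build_event_table(_mk_reads([edited], "tx"), [], site, cut)
    cells = set(table.counts)
    assert len(cells) == 2
    assert all(c == [1, 0] for c in table.counts.values())
    assert table.tx_read_cells["tx0"] == frozenset(cells)


def test_event_table_perfect_reads_empty(panel2):
    site = panel2[0]
    cut = locate_cut_site(site)
    table = build_event_table(
        _mk_reads([site.amplicon] * 5, "tx"), _mk_reads([site.amplicon] * 5, "m"),
        site, cut,
    )
    assert table.counts == {}
    assert table.n_tx == 5 and table.n_m == 5


def test_deletion_calls_reconstruct_read(panel2):
    """Applying the reported deletions to the amplicon regenerates the read."""
    site = panel2[0]
    cut = locate_cut_site(site)
    for length in (1, 2, 4, 7):
        read = apply_edit(site.amplicon, cut, "deletion", length)
        aln = needleman_wunsch(read, site.amplicon, AlignParams(), cut)
        calls = extract_indels(aln, (0, len(site.amplicon) - 1))
        rebuilt = site.amplicon
        for c in sorted(calls, key=lambda c: -c.position):
            assert c.kind == "deletion"
            rebuilt = rebuilt[: c.position] + rebuilt[c.position + c.length:]
        assert rebuilt == read


def test_event_cell_counts_bounded_by_totals(panel2):
    site = panel2[0]
    cut = locate_cut_site(site)
    reads = [Read(f"t{k}", apply_edit(site.amplicon, cut, "deletion", 2)) for k in range(8)]
    table = build_event_table(reads, reads[:3], site, cut)
    for n_tx, n_m in table.counts.values():
        assert n_tx <= table.n_tx and n_m <= table.n_m
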