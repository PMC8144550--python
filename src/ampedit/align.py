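"""Global read-to-amplicon alignment and indel-event extraction.

Alignment is Needleman-Wunsch with affine gap penalties (Gotoh recurrences,
row-vectorized in numpy). Affine penalties consolidate scattered gap columns
into single indel events, which is what the downstream per-(type, position)
classifier consumes.

Indel placement is frequently ambiguous: in repetitive context (e.g. a
homopolymer spanning the cut-site) many co-optimal alignments exist that
put the same gap at different reference positions. Since the biological
expectation is a double-strand break at the cut-site, co-optimal gap
placements are resolved by sliding each gap run, score-neutrally, to the
position closest to the expected cut index (ties broken leftmost).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .panel import CutSite, Read, SiteConfig

NEG = -1e30  # effectively -infinity for the DP


@dataclass
class AlignParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -20.0   # cost of the first column of a gap run
    gap_extend: float = -1.0  # cost of each further column

    def sub(self, a: str, b: str) -> float:
        return self.match if a == b else self.mismatch


@dataclass
class Alignment:
    ref_aln: str
    read_aln: str
    score: float


@dataclass(frozen=True)
class IndelCall:
    """kind: 'deletion' | 'insertion'; position: 0-based reference index of the
    5'-most deleted base (deletions) or of the base immediately 5' of the
    inserted sequence (insertions)."""

    kind: str
    length: int
    position: int


def needleman_wunsch(
    read: str,
    amplicon: str,
    params: AlignParams | None = None,
    cut_site: CutSite | int | None = None,
) -> Alignment:
    """Optimal global alignment; gaps placed nearest the cut-site among
    score-equivalent placements."""
    params = params or AlignParams()
    if not read or not amplicon:
        raise ValueError("needleman_wunsch requires two non-empty sequences")
    M, D, I = _gotoh_matrices(read, amplicon, params)
    ref_aln, read_aln, score = _traceback(read, amplicon, params, M, D, I)
    cut = cut_site.index if isinstance(cut_site, CutSite) else cut_site
    if cut is not None:
        ref_aln, read_aln = _slide_gaps_toward(ref_aln, read_aln, params, cut)
    return Alignment(ref_aln=ref_aln, read_aln=read_aln, score=score)


def _gotoh_matrices(read: str, ref: str, p: AlignParams):
    """Full DP matrices. Rows index the read (i), columns the reference (j).

    M[i, j]: read[i-1] aligned to ref[j-1].
    D[i, j]: ref[j-1] deleted (gap in the read row).
    I[i, j]: read[i-1] inserted (gap in the reference row).
    """
    n, m = len(read), len(ref)
    go, ge = p.gap_open, p.gap_extend
    M = np.full((n + 1, m + 1), NEG)
    D = np.full((n + 1, m + 1), NEG)
    I = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    D[0, 1:] = go + ge * (j - 1)
    i = np.arange(1, n + 1)
    I[1:, 0] = go + ge * (i - 1)

    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], D[i - 1]), I[i - 1])
        sub = np.where(ref_arr == read_arr[i - 1], p.match, p.mismatch)
        M[i, 1:] = prev_best[:-1] + sub
        I[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], D[i - 1, 1:]) + go, I[i - 1, 1:] + ge
        )
        # D[i, j] = max over k < j of (max(M[i,k], I[i,k]) + go + ge*(j-1-k)):
        # a running maximum, computed with one accumulate.
        t = np.maximum(M[i], I[i]) - ge * js
        run = np.maximum.accumulate(t[:-1])
        D[i, 1:] = np.maximum(D[i, 1:], go + ge * (js[1:] - 1) + run)
    return M, D, I


def _traceback(read: str, ref: str, p: AlignParams, M, D, I):
    n, m = len(read), len(ref)
    go, ge = p.gap_open, p.gap_extend
    states = {"M": M, "D": D, "I": I}
    # Deterministic preference: aligned columns first, then deletions, insertions.
    order = ("M", "D", "I")
    i, j = n, m
    state = max(order, key=lambda s: states[s][n, m])
    score = float(states[state][n, m])
    ref_out, read_out = [], []
    while i > 0 or j > 0:
        if state == "M":
            ref_out.append(ref[j - 1])
            read_out.append(read[i - 1])
            target = M[i, j] - p.sub(ref[j - 1], read[i - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = _pick(order, states, i, j, target)
        elif state == "D":
            ref_out.append(ref[j - 1])
            read_out.append("-")
            val = D[i, j]
            j -= 1
            # Prefer extending the gap on ties so runs stay contiguous.
            if D[i, j] + ge == val:
                state = "D"
            elif M[i, j] + go == val:
                state = "M"
            elif I[i, j] + go == val:
                state = "I"
            else:  # leading gap boundary
                state = "D"
        else:  # I
            ref_out.append("-")
            read_out.append(read[i - 1])
            val = I[i, j]
            i -= 1
            if I[i, j] + ge == val:
                state = "I"
            elif M[i, j] + go == val:
                state = "M"
            elif D[i, j] + go == val:
                state = "D"
            else:
                state = "I"
    return "".join(reversed(ref_out)), "".join(reversed(read_out)), score


def _pick(order, states, i, j, target):
    for s in order:
        if states[s][i, j] == target:
            return s
    # Floating-point slack should never be needed with integral scores, but
    # fall back to the best-valued state rather than erroring.
    return max(order, key=lambda s: states[s][i, j])


def _gap_runs(ref_aln: str, read_aln: str):
    """Maximal runs of gap columns as (start_col, end_col, kind)."""
    runs = []
    k = 0
    while k < len(ref_aln):
        if read_aln[k] == "-":
            start = k
            while k < len(ref_aln) and read_aln[k] == "-":
                k += 1
            runs.append((start, k, "deletion"))
        elif ref_aln[k] == "-":
            start = k
            while k < len(ref_aln) and ref_aln[k] == "-":
                k += 1
            runs.append((start, k, "insertion"))
        else:
            k += 1
    return runs


def _slide_gaps_toward(ref_aln: str, read_aln: str, p: AlignParams, cut: int):
    """Move each gap run among its score-equivalent placements to the position
    nearest ``cut`` (reference coordinates), ties leftmost."""
    ref_cols = list(ref_aln)
    read_cols = list(read_aln)

    changed = True
    while changed:
        changed = False
        for start, end, kind in _gap_runs("".join(ref_cols), "".join(read_cols)):
            pos = _run_ref_position(ref_cols, start, kind)
            best_shift = 0
            best_key = (abs(pos - cut), pos)
            for direction in (-1, 1):
                shift, s, e = 0, start, end
                while True:
                    ok = _try_shift(ref_cols, read_cols, s, e, kind, direction, p, dry=True)
                    if not ok:
                        break
                    shift += direction
                    s += direction
                    e += direction
                    new_pos = pos + shift
                    key = (abs(new_pos - cut), new_pos)
                    if key < best_key:
                        best_key, best_shift = key, shift
            if best_shift != 0:
                step = 1 if best_shift > 0 else -1
                s, e = start, end
                for _ in range(abs(best_shift)):
                    _try_shift(ref_cols, read_cols, s, e, kind, step, p, dry=False)
                    s += step
                    e += step
                changed = True
                break  # runs moved; recompute run list
    return "".join(ref_cols), "".join(read_cols)


def _run_ref_position(ref_cols, start, kind) -> int:
    """Reference position reported for a gap run starting at column ``start``."""
    consumed = sum(1 for c in ref_cols[:start] if c != "-")
    if kind == "deletion":
        return consumed  # 5'-most deleted base
    return consumed - 1  # base immediately 5' of the insertion


def _try_shift(ref_cols, read_cols, start, end, kind, direction, p: AlignParams, dry: bool):
    """Shift the gap run [start, end) by one column; score-neutral moves only.

    Returns True when the shift is valid (and applies it unless ``dry``).
    """
    n = len(ref_cols)
    if direction > 0:
        nb = end
        if nb >= n or ref_cols[nb] == "-" or read_cols[nb] == "-":
            return False
        if kind == "deletion":
            # Deleted block moves right: the read base aligned at `end`
            # re-pairs with ref_cols[start]; reference order is untouched.
            delta = p.sub(ref_cols[start], read_cols[nb]) - p.sub(ref_cols[nb], read_cols[nb])
            if delta != 0:
                return False
            if not dry:
                moved = read_cols.pop(nb)
                read_cols.insert(start, moved)
        else:
            # Inserted block moves right: the reference base aligned at `end`
            # re-pairs with the first inserted read base; read order untouched.
            delta = p.sub(ref_cols[nb], read_cols[start]) - p.sub(ref_cols[nb], read_cols[nb])
            if delta != 0:
                return False
            if not dry:
                moved = ref_cols.pop(nb)
                ref_cols.insert(start, moved)
        return True
    nb = start - 1
    if nb < 0 or ref_cols[nb] == "-" or read_cols[nb] == "-":
        return False
    if kind == "deletion":
        delta = p.sub(ref_cols[end - 1], read_cols[nb]) - p.sub(ref_cols[nb], read_cols[nb])
        if delta != 0:
            return False
        if not dry:
            moved = read_cols.pop(nb)
            read_cols.insert(end - 1, moved)
    else:
        delta = p.sub(ref_cols[nb], read_cols[end - 1]) - p.sub(ref_cols[nb], read_cols[nb])
        if delta != 0:
            return False
        if not dry:
            moved = ref_cols.pop(nb)
            ref_cols.insert(end - 1, moved)
    return True


def extract_indels(alignment: Alignment, window: tuple[int, int]) -> list[IndelCall]:
    """Indel calls from an alignment, restricted to reference positions in the
    inclusive ``window``. Substitution columns are ignored."""
    lo, hi = window
    calls = []
    ref_pos = -1  # last consumed reference index
    k = 0
    ra, qa = alignment.ref_aln, alignment.read_aln
    n = len(ra)
    while k < n:
        if qa[k] == "-":
            start_pos = ref_pos + 1
            length = 0
            while k < n and qa[k] == "-":
                length += 1
                ref_pos += 1
                k += 1
            if lo <= start_pos <= hi:
                calls.append(IndelCall("deletion", length, start_pos))
        elif ra[k] == "-":
            pos = ref_pos
            length = 0
            while k < n and ra[k] == "-":
                length += 1
                k += 1
            if lo <= pos <= hi:
                calls.append(IndelCall("insertion", length, pos))
        else:
            ref_pos += 1
            k += 1
    return calls


def count_substitutions(alignment: Alignment) -> int:
    return sum(
        1
        for a, b in zip(alignment.ref_aln, alignment.read_aln)
        if a != "-" and b != "-" and a != b
    )


@dataclass
class EventTable:
    """Per-site (indel type, position) count table inside the classification
    window. Cells are keyed ``(kind, length_class, position)``; a read
    contributes at most once per cell but may hit several cells."""

    site_id: str
    window: tuple[int, int]  # inclusive reference-index range
    n_tx: int
    n_m: int
    counts: dict[tuple, list[int]] = field(default_factory=dict)  # cell -> [n_tx, n_m]
    tx_read_cells: dict[str, frozenset] = field(default_factory=dict)
    substitution_columns: int = 0  # diagnostic only; not editing evidence

    def cell_counts(self, cell) -> tuple[int, int]:
        c = self.counts.get(cell, (0, 0))
        return c[0], c[1]


def length_class(length: int, max_len_class: int = 30) -> int:
    """Exact lengths up to ``max_len_class - 1``; longer events pool at
    ``max_len_class``."""
    return min(length, max_len_class)


def build_event_table(
    tx_reads: Sequence[Read],
    m_reads: Sequence[Read],
    site: SiteConfig,
    cut_site: CutSite,
    params: AlignParams | None = None,
    window_half_width: int = 10,
    max_len_class: int = 30,
) -> EventTable:
    """Align both pools to the amplicon and accumulate windowed indel events.

    Alignment results are cached per unique read sequence; amplicon-identical
    reads short-circuit without a DP pass.
    """
    params = params or AlignParams()
    amp = site.amplicon
    lo = max(0, cut_site.index - window_half_width)
    hi = min(len(amp) - 1, cut_site.index + window_half_width)
    table = EventTable(site_id=site.site_id, window=(lo, hi),
                       n_tx=len(tx_reads), n_m=len(m_reads))

    cache: dict[str, tuple[frozenset, int]] = {}

    def cells_for(seq: str) -> tuple[frozenset, int]:
        hit = cache.get(seq)
        if hit is not None:
            return hit
        if seq == amp:
            result = (frozenset(), 0)
        else:
            aln = needleman_wunsch(seq, amp, params, cut_site)
            calls = extract_indels(aln, (lo, hi))
            cells = frozenset(
                (c.kind, length_class(c.length, max_len_class), c.position) for c in calls
            )
            result = (cells, count_substitutions(aln))
        cache[seq] = result
        return result

    for pool_idx, reads in ((0, tx_reads), (1, m_reads)):
        for read in reads:
            cells, subs = cells_for(read.sequence)
            table.substitution_columns += subs
            for cell in cells:
                table.counts.setdefault(cell, [0, 0])[pool_idx] += 1
            if pool_idx == 0 and cells:
                table.tx_read_cells[read.read_id] = cells
    return table


def event_table_frame(table: EventTable):
    """Event table as a tidy DataFrame (for the optional per-site dump)."""
    import pandas as pd

    rows = [
        {
            "site_id": table.site_id,
            "kind": kind,
            "length_class": lc,
            "position": pos,
            "n_tx": c[0],
            "n_m": c[1],
        }
        for (kind, lc, pos), c in sorted(table.counts.items())
    ]
    return pd.DataFrame(rows, columns=["site_id", "kind", "length_class", "position", "n_tx", "n_m"])
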