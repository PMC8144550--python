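"""Bayesian MAP classification of indel events: edit vs background noise.

For every (indel type, reference position) cell the treatment/mock count
pair (n_Tx, n_M) is scored under two generative models:

* **no edit** — indels of this type/position are equally likely in a mock
  read as in a treatment read, so n_Tx out of the n_Tx + n_M observed
  events follows a hypergeometric draw of N_Tx reads from the pooled
  N_Tx + N_M reads;
* **edit** — most events at an edited cell arise in treatment, so
  n_Tx ~ Binomial(n_Tx + n_M, q) with q close to 1.

The cell is labeled an edit when

    P(edit) * P(n_Tx, n_M | edit)  >  P(no edit) * P(n_Tx, n_M | no edit),

with a position-dependent prior that peaks at the expected cut-site (0.5)
and decays with distance (1e-1 down to 1e-4 at the window edge). Non-zero
off-cut priors are what make alternative cut-sites detectable. All
likelihoods are evaluated in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom, hypergeom

from .align import EventTable
from .errors import ConfigError
from .panel import CutSite


@dataclass
class ClassifyParams:
    window_half_width: int = 10      # the 20-bp classification window: cut +/- 10
    p_edit_cut: float = 0.5          # prior at the expected cut-site
    p_edit_near: float = 1e-1        # prior at distance 1
    p_edit_far: float = 1e-4         # prior at the window edge
    prior_override: Sequence[float] | None = None  # per-position priors, length 2*hw+1
    q_default: float = 0.95
    q_min: float = 0.90
    q_max: float = 0.999
    q_min_evidence: int = 50         # n_Tx + n_M needed for a cell to inform q
    q_cut_tolerance: int = 2         # cells within this distance of the cut inform q


@dataclass
class PriorLadder:
    """Per-position P(edit) over the classification window."""

    cut_index: int
    positions: np.ndarray  # reference indices, ascending
    priors: np.ndarray     # same length, values in (0, 1)

    def prior_at(self, position: int) -> float:
        idx = int(position) - int(self.positions[0])
        if idx < 0 or idx >= len(self.priors):
            raise ValueError(f"position {position} outside the classification window")
        return float(self.priors[idx])


def prior_for_distance(d: int, half_width: int, params: ClassifyParams) -> float:
    """Prior ladder value at distance ``d`` from the cut-site.

    0.5 at d=0; for d >= 1 the prior is log-linear in d between 1e-1 (d=1)
    and 1e-4 (d=half_width)."""
    if d == 0:
        return params.p_edit_cut
    if half_width <= 1:
        return params.p_edit_near
    lo = math.log10(params.p_edit_near)
    hi = math.log10(params.p_edit_far)
    frac = (d - 1) / (half_width - 1)
    return 10.0 ** (lo + (hi - lo) * frac)


def build_prior_ladder(
    window: tuple[int, int],
    cut_site: CutSite | int,
    params: ClassifyParams | None = None,
) -> PriorLadder:
    """Prior ladder over the inclusive reference-index ``window``.

    ``params.prior_override`` replaces the built-in ladder entirely; it must
    have one value in (0, 1) per window position.
    """
    params = params or ClassifyParams()
    cut = cut_site.index if isinstance(cut_site, CutSite) else int(cut_site)
    lo, hi = window
    positions = np.arange(lo, hi + 1)
    if params.prior_override is not None:
        priors = np.asarray(params.prior_override, dtype=float)
        if len(priors) != len(positions):
            raise ConfigError(
                f"prior override has length {len(priors)}, window needs {len(positions)}"
            )
        if np.any(priors <= 0.0) or np.any(priors >= 1.0):
            raise ConfigError("prior override values must lie strictly in (0, 1)")
    else:
        hw = params.window_half_width
        priors = np.array(
            [prior_for_distance(abs(int(p) - cut), hw, params) for p in positions]
        )
    return PriorLadder(cut_index=cut, positions=positions, priors=priors)


def loglik_no_edit(n_tx: int, n_m: int, N_tx: int, N_m: int) -> float:
    """Log hypergeometric point mass of the no-edit model:
    HG(b=n_tx; N=N_tx+N_m, B=n_tx+n_m, n=N_tx)."""
    if not (0 <= n_tx <= N_tx and 0 <= n_m <= N_m):
        raise ValueError(
            f"counts out of bounds: n_tx={n_tx}, n_m={n_m}, N_tx={N_tx}, N_m={N_m}"
        )
    if n_tx + n_m == 0:
        return 0.0
    return float(hypergeom.logpmf(n_tx, N_tx + N_m, n_tx + n_m, N_tx))


def loglik_edit(n_tx: int, n_m: int, q: float) -> float:
    """Log binomial point mass of the edit model: Binom(n_tx + n_m, q) at n_tx."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie strictly in (0, 1), got {q}")
    if n_tx < 0 or n_m < 0:
        raise ValueError("counts must be non-negative")
    if n_tx + n_m == 0:
        return 0.0
    return float(binom.logpmf(n_tx, n_tx + n_m, q))


@dataclass(frozen=True)
class ClassifierDecision:
    kind: str
    length_class: int
    position: int
    n_tx: int
    n_m: int
    log_posterior_edit: float
    log_posterior_noedit: float
    label: str  # "edit" | "noise"


@dataclass(frozen=True)
class EditModelParams:
    q: float
    n_informative_cells: int = 0
    source: str = "default"  # "estimated" | "clamped" | "default"


def estimate_q(
    event_tables: Mapping[str, EventTable],
    cut_sites: Mapping[str, CutSite],
    on_target_ids: Iterable[str],
    params: ClassifyParams | None = None,
) -> EditModelParams:
    """Pooled treatment fraction over well-supported cut-site-proximal cells
    of the on-target loci, clamped to [q_min, q_max]. Falls back to
    ``q_default`` when no cell qualifies."""
    params = params or ClassifyParams()
    tot_tx = tot = n_cells = 0
    for sid in on_target_ids:
        table = event_tables.get(sid)
        if table is None:
            continue
        cut = cut_sites[sid].index
        for (kind, lc, pos), (n_tx, n_m) in table.counts.items():
            if abs(pos - cut) > params.q_cut_tolerance:
                continue
            if n_tx + n_m < params.q_min_evidence:
                continue
            tot_tx += n_tx
            tot += n_tx + n_m
            n_cells += 1
    if n_cells == 0 or tot == 0:
        return EditModelParams(q=params.q_default, n_informative_cells=0, source="default")
    raw = tot_tx / tot
    q = min(max(raw, params.q_min), params.q_max)
    source = "estimated" if q == raw else "clamped"
    return EditModelParams(q=q, n_informative_cells=n_cells, source=source)


def classify_cell(
    n_tx: int,
    n_m: int,
    N_tx: int,
    N_m: int,
    prior: float,
    q: float,
    kind: str = "",
    length_class: int = 0,
    position: int = 0,
) -> ClassifierDecision:
    """MAP decision for one cell. Cells with no treatment evidence
    short-circuit to noise; exact posterior ties are resolved as noise
    (conservative)."""
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must lie strictly in (0, 1), got {prior}")
    if n_tx == 0:
        return ClassifierDecision(
            kind, length_class, position, n_tx, n_m,
            log_posterior_edit=-math.inf, log_posterior_noedit=0.0, label="noise",
        )
    lp_edit = math.log(prior) + loglik_edit(n_tx, n_m, q)
    lp_noedit = math.log1p(-prior) + loglik_no_edit(n_tx, n_m, N_tx, N_m)
    label = "edit" if lp_edit > lp_noedit else "noise"
    return ClassifierDecision(
        kind, length_class, position, n_tx, n_m,
        log_posterior_edit=lp_edit, log_posterior_noedit=lp_noedit, label=label,
    )


def classify_site(
    table: EventTable,
    ladder: PriorLadder,
    q: float,
) -> list[ClassifierDecision]:
    """Classify every populated cell of a site's event table."""
    decisions = []
    for (kind, lc, pos), (n_tx, n_m) in sorted(table.counts.items()):
        prior = ladder.prior_at(pos)
        decisions.append(
            classify_cell(
                n_tx, n_m, table.n_tx, table.n_m, prior, q,
                kind=kind, length_class=lc, position=pos,
            )
        )
    return decisions


def mark_edited_reads(
    table: EventTable,
    decisions: Sequence[ClassifierDecision],
) -> set[str]:
    """Treatment read ids carrying at least one edit-labeled event.

    Mock reads are never marked; all edit-classified treatment reads count
    as edits, with no mock subtraction.
    """
    edit_cells = {
        (d.kind, d.length_class, d.position) for d in decisions if d.label == "edit"
    }
    if not edit_cells:
        return set()
    return {
        rid for rid, cells in table.tx_read_cells.items() if cells & edit_cells
    }
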