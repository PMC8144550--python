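"""Editing-activity estimation: point estimate, Wald confidence interval,
active/inactive call, and the cross-condition concordance test.

Activity at a locus is the fraction of treatment reads classified as
edited. The interval is the plain normal-approximation (Wald) interval

    p_hat +/- z_{1 - alpha/2} * sqrt(p_hat (1 - p_hat) / N_Tx),

clamped to [0, 1], with no continuity correction. A locus is "active" when
its activity reaches a configurable threshold (0.1% by convention in the
off-target literature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import binom, norm


@dataclass
class SiteResult:
    site_id: str
    n_tx: int
    n_m: int
    edited_reads: int
    activity: float   # fraction in [0, 1]
    ci_low: float
    ci_high: float
    active: bool
    warning: str | None = None


def editing_activity(
    edited: int,
    n_tx: int,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """(activity, ci_low, ci_high) as fractions; Wald interval at level alpha."""
    if edited < 0 or (n_tx and edited > n_tx):
        raise ValueError(f"edited={edited} out of range for N_Tx={n_tx}")
    if n_tx == 0:
        return 0.0, 0.0, 0.0
    p_hat = edited / n_tx
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(p_hat * (1.0 - p_hat) / n_tx)
    return p_hat, max(0.0, p_hat - half), min(1.0, p_hat + half)


def site_result(
    site_id: str,
    n_tx: int,
    n_m: int,
    edited: int,
    alpha: float = 0.05,
    active_threshold: float = 1e-3,
) -> SiteResult:
    warning = None
    if n_tx == 0:
        warning = "no treatment reads; activity undefined, reported as 0"
    activity, lo, hi = editing_activity(edited, n_tx, alpha)
    return SiteResult(
        site_id=site_id,
        n_tx=n_tx,
        n_m=n_m,
        edited_reads=edited,
        activity=activity,
        ci_low=lo,
        ci_high=hi,
        active=classify_active(activity, active_threshold),
        warning=warning,
    )


def classify_active(activity: float, threshold: float = 1e-3) -> bool:
    return activity >= threshold


def concordance_test(
    instance_pairs: Sequence[tuple[float, float]],
) -> tuple[int, int, float]:
    """Monotone concordance of activity rates across experimental strength.

    Each pair is (rate under the weaker condition, rate under the stronger
    condition); a pair is concordant when the stronger condition's rate is
    at least the weaker one's (ties concordant). Under the null of no real
    activity the concordant count is Binomial(n, 0.5); returns
    (k concordant, n, one-sided upper-tail p-value, exact).
    """
    n = len(instance_pairs)
    if n == 0:
        raise ValueError("concordance_test requires at least one instance pair")
    k = sum(1 for weak, strong in instance_pairs if strong >= weak)
    p = float(binom.sf(k - 1, n, 0.5))  # P(X >= k)
    return k, n, p
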