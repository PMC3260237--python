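"""Mortality-detection probability from single vs dual tag returns.

Dual-implanted animals report a death through either of two independently
failing satellite transmitters.  The ratio of single to dual data returns
identifies the per-tag uplink failure probability

    P_fail = C_single / (C_single + 2 C_dual),

from which the event detection probability ``P_detect = 1 - P_fail**2`` and
the correction factor ``F = 1 / P_detect`` follow.  The corrected number of
mortality events is ``E_corr = F * (detected events)``.  Confidence ranges
for ``P_fail`` (and hence ``E_corr``) are obtained by inverting a Monte
Carlo simulation of per-tag failures over a fine grid of candidate failure
probabilities.

The module also provides the two small-sample 2x2 comparisons used to check
homogeneity of detection across strata: the simple cross-ratio odds ratio
and a two-tailed Fisher exact test (point-probability method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom


@dataclass(frozen=True)
class ReturnCounts:
    """Tally of single vs dual tag data returns for one stratum."""

    n_single: int
    n_dual: int
    stratum: str = "pooled"

    def __post_init__(self) -> None:
        if self.n_single < 0 or self.n_dual < 0:
            raise ValueError("return counts must be non-negative")

    @property
    def n_events(self) -> int:
        return self.n_single + self.n_dual

    def pooled_with(self, other: "ReturnCounts", stratum: str = "pooled") -> "ReturnCounts":
        return ReturnCounts(self.n_single + other.n_single, self.n_dual + other.n_dual, stratum)


@dataclass
class DetectionEstimate:
    """Point estimates and (optional) Monte Carlo ranges for detection.

    Invariants: ``p_detect = 1 - p_fail**2`` and ``f_correction * p_detect = 1``
    hold to machine precision.  ``degenerate`` marks the boundary case of no
    dual returns with at least one single return (``p_fail = 1``, F undefined).
    """

    p_fail: float
    p_detect: float
    f_correction: float
    degenerate: bool = False
    p_fail_ci95: tuple[float, float] | None = None
    e_corr: float | None = None
    e_corr_integer: int | None = None
    e_corr_ci95: tuple[int, int] | None = None


def estimate_pfail(counts: ReturnCounts) -> DetectionEstimate:
    """Estimate per-tag uplink failure and event detection probability.

    Raises ``ValueError`` when no returns are available.  With dual returns
    absent but singles present the estimate is the degenerate boundary
    ``p_fail = 1`` (``p_detect = 0``, correction factor undefined/infinite).
    """
    if counts.n_events < 1:
        raise ValueError(f"stratum {counts.stratum!r}: no returns to estimate from")
    p_fail = counts.n_single / (counts.n_single + 2 * counts.n_dual)
    p_detect = 1.0 - p_fail**2
    if p_detect == 0.0:
        return DetectionEstimate(p_fail=1.0, p_detect=0.0, f_correction=math.inf, degenerate=True)
    return DetectionEstimate(p_fail=p_fail, p_detect=p_detect, f_correction=1.0 / p_detect)


def correct_event_count(detected_events: int, est: DetectionEstimate) -> tuple[float, int]:
    """Inflate a detected event count by the correction factor F.

    Returns ``(e_corr, integer portion)``.  The integer portion (floor) is
    what downstream rate estimation uses, since animals do not die in
    fractional numbers.
    """
    if detected_events < 0:
        raise ValueError("detected_events must be >= 0")
    e_corr = est.f_correction * detected_events
    return e_corr, int(math.floor(e_corr))


def mc_pfail_ci(
    counts: ReturnCounts,
    detected_events: int | None = None,
    iterations: int = 2500,
    rng_seed: int | np.random.Generator = 0,
    grid_step: float = 0.0025,
    alpha: float = 0.05,
) -> tuple[tuple[float, float], tuple[int, int]]:
    """Monte Carlo 95% range for P_fail and the implied E_corr interval.

    For each candidate per-tag failure probability on a fine grid over
    [0, 1), the per-tag failure process is simulated across the observed
    number of dual-tag deployments (a deployment returns single when exactly
    one of its two tags fails).  A candidate is accepted when the observed
    single-return count falls within the central ``1 - alpha`` of its
    simulated distribution; the reported range is the min/max accepted
    candidate.  The range is propagated through F to an integer interval for
    the corrected event count (rounded outward).
    """
    if counts.n_events < 1:
        raise ValueError("degenerate counts: nothing to simulate")
    if counts.n_dual == 0:
        raise ValueError("no dual returns: P_fail unidentifiable by simulation")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if detected_events is None:
        detected_events = counts.n_events
    rng = np.random.default_rng(rng_seed)
    n = counts.n_events
    grid = np.arange(0.0, 1.0, grid_step)
    accepted: list[float] = []
    tail = alpha / 2.0
    for p in grid:
        # P(single | detected): exactly one of two tags fails, given not both
        q_single = 2.0 * p / (1.0 + p)
        singles = rng.binomial(n, q_single, size=iterations)
        p_ge = np.mean(singles >= counts.n_single)
        p_le = np.mean(singles <= counts.n_single)
        if p_ge >= tail and p_le >= tail:
            accepted.append(float(p))
    if not accepted:
        raise ValueError("no candidate failure probability consistent with the data")
    p_lo, p_hi = min(accepted), max(accepted)
    f_lo = 1.0 / (1.0 - p_lo**2)
    f_hi = 1.0 / (1.0 - p_hi**2)
    e_lo = int(math.floor(f_lo * detected_events))
    e_hi = int(math.ceil(f_hi * detected_events))
    return (p_lo, p_hi), (e_lo, e_hi)


def full_detection_estimate(
    counts: ReturnCounts,
    detected_events: int,
    iterations: int = 2500,
    rng_seed: int | np.random.Generator = 0,
) -> DetectionEstimate:
    """Point estimate plus Monte Carlo ranges in one DetectionEstimate."""
    est = estimate_pfail(counts)
    est.e_corr, est.e_corr_integer = correct_event_count(detected_events, est)
    est.p_fail_ci95, est.e_corr_ci95 = mc_pfail_ci(
        counts, detected_events=detected_events, iterations=iterations, rng_seed=rng_seed
    )
    return est


def odds_ratio(table) -> float:
    """Cross-ratio odds ratio (a/b)/(c/d) for rows (a, b), (c, d).

    The orientation is row 1 versus row 2 as supplied by the caller.
    Raises ``ValueError`` on a zero denominator.
    """
    (a, b), (c, d) = np.asarray(table, dtype=float)
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if b == 0 or d == 0 or c == 0:
        raise ValueError("odds ratio undefined: zero denominator in table")
    return (a / b) / (c / d)


def fisher_exact_two_tailed(table) -> float:
    """Two-tailed Fisher exact p-value by the point-probability method.

    Sums hypergeometric probabilities, over all tables with the observed
    margins, whose point probability does not exceed that of the observed
    table (within a small relative tolerance for float ties).
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative integers")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    return float(np.sum(pmf[pmf <= p_obs * (1.0 + 1e-9)]))
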