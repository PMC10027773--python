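"""Conservative dual-criteria (CDC) structured visual aid.

The CDC rule projects two reference lines from baseline into the
treatment phase: a flat line at the phase-A mean and the OLS trend line
fitted to phase A, both raised by 0.25 baseline standard deviations
(hence "conservative").  Phase-B points falling strictly above *both*
lines are counted; the graph is declared to show an effect when that
count reaches the critical value of a one-sided Binomial(n_b, 0.5) test
at alpha = 0.05.  With fewer than five treatment points no count can
reach significance and the rule is inapplicable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.05
SD_SHIFT = 0.25


class UnattainableCriterionError(ValueError):
    """Phase B is too short for any count of points to reach significance."""


@dataclass(frozen=True)
class CDCResult:
    """Outcome of the CDC rule on one AB graph."""

    mean_line_b: np.ndarray
    trend_line_b: np.ndarray
    points_above: int
    criterion: int
    effect: bool


def binomial_criterion(
    n_b: int, alpha: float = DEFAULT_ALPHA, method: str = "published"
) -> int | None:
    """Critical count of phase-B points above both lines.

    Two variants of the one-sided Binomial(n_b, 0.5) criterion:

    * ``"published"`` (default) — the criterion table in field use,
      generated by the normal approximation to the binomial test:
      ``ceil(n/2 + z_{1-alpha} * sqrt(n)/2)``.  For the phase-B lengths
      used here this gives 5 of 5 and 8 of 10 points, the counts
      consistent with reported CDC error rates; defined for n_b >= 5.
    * ``"exact"`` — smallest ``k`` with ``P(X >= k) < alpha`` from the
      exact binomial tail.  Slightly stricter (9 of 10 points).

    Returns None when no count of points can reach significance.
    """
    if n_b < 1:
        raise ValueError(f"n_b must be >= 1, got {n_b}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if method == "published":
        if n_b < 5:
            return None
        z = stats.norm.ppf(1 - alpha)
        k = int(np.ceil(n_b / 2 + z * np.sqrt(n_b) / 2))
        return k if k <= n_b else None
    if method == "exact":
        k = np.arange(n_b + 1)
        tail = stats.binom.sf(k - 1, n_b, 0.5)  # P(X >= k)
        attainable = np.nonzero(tail < alpha)[0]
        return int(attainable[0]) if attainable.size else None
    raise ValueError(f"method must be 'published' or 'exact', got {method!r}")


def cdc_decision(
    phase_a: np.ndarray,
    phase_b: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    direction: str = "increase",
    conservative: bool = True,
    criterion_method: str = "published",
) -> CDCResult:
    """Apply the CDC rule to one AB graph.

    The trend line is fitted on phase-A session indices ``0..L-1`` and
    evaluated on the continuing indices ``L..L+n_b-1``.  Both lines are
    shifted by ``0.25 * SD(phase_a)`` (sample SD, n-1 denominator) toward
    the expected change: upward for ``direction="increase"`` (the
    default, matching an injected positive effect), downward for
    ``direction="decrease"``.  ``conservative=False`` drops the shift
    (the plain dual-criteria variant).  Points exactly on a line do not
    count.
    """
    phase_a = np.asarray(phase_a, dtype=float).ravel()
    phase_b = np.asarray(phase_b, dtype=float).ravel()
    if len(phase_a) < 2:
        raise ValueError("phase A needs at least 2 points to fit a trend line")
    if direction not in ("increase", "decrease"):
        raise ValueError(f"direction must be 'increase' or 'decrease', got {direction!r}")
    criterion = binomial_criterion(len(phase_b), alpha, criterion_method)
    if criterion is None:
        raise UnattainableCriterionError(
            f"no count of points can reach significance with n_b={len(phase_b)} "
            f"at alpha={alpha}"
        )
    L = len(phase_a)
    idx = np.arange(L, dtype=float)
    xc = idx - idx.mean()
    slope = phase_a @ xc / (xc @ xc)
    intercept = phase_a.mean() - slope * idx.mean()
    b_idx = np.arange(L, L + len(phase_b), dtype=float)
    shift = SD_SHIFT * phase_a.std(ddof=1) if conservative else 0.0
    sgn = 1.0 if direction == "increase" else -1.0
    mean_line = np.full(len(phase_b), phase_a.mean() + sgn * shift)
    trend_line = intercept + slope * b_idx + sgn * shift
    if direction == "increase":
        above = (phase_b > mean_line) & (phase_b > trend_line)
    else:
        above = (phase_b < mean_line) & (phase_b < trend_line)
    points_above = int(above.sum())
    return CDCResult(
        mean_line_b=mean_line,
        trend_line_b=trend_line,
        points_above=points_above,
        criterion=criterion,
        effect=points_above >= criterion,
    )


def cdc_effects(
    phase_a: np.ndarray,
    phase_b: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    criterion_method: str = "published",
) -> np.ndarray:
    """Vectorised CDC decisions for a stack of graphs with equal phase lengths.

    ``phase_a`` is ``(n, L)``, ``phase_b`` is ``(n, n_b)``; returns a
    boolean effect vector.  Equivalent row-by-row to
    :func:`cdc_decision` with the default settings (checked by the test
    suite's oracle-equivalence property).
    """
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    n, L = phase_a.shape
    n_b = phase_b.shape[1]
    criterion = binomial_criterion(n_b, alpha, criterion_method)
    if criterion is None:
        raise UnattainableCriterionError(
            f"no count of points can reach significance with n_b={n_b} at alpha={alpha}"
        )
    idx = np.arange(L, dtype=float)
    xc = idx - idx.mean()
    slopes = phase_a @ xc / (xc @ xc)
    intercepts = phase_a.mean(axis=1) - slopes * idx.mean()
    b_idx = np.arange(L, L + n_b, dtype=float)
    shift = SD_SHIFT * phase_a.std(axis=1, ddof=1)
    mean_line = (phase_a.mean(axis=1) + shift)[:, None]
    trend_line = intercepts[:, None] + slopes[:, None] * b_idx + shift[:, None]
    above = (phase_b > mean_line) & (phase_b > trend_line)
    return above.sum(axis=1) >= criterion
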