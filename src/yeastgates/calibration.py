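"""Control-calibrated high/low GFP threshold.

The high/low cut-off is chosen from per-well mean log10 GFP values of
the positive (NOR00, constitutively high) and negative (WT,
non-fluorescent) control wells, by minimizing the mean "wrong-direction"
distance: how far negative controls sit above the candidate threshold
plus how far positive controls sit below it, divided by the total number
of control wells.

The cost is piecewise linear and convex in the threshold, so the global
minimum is found exactly by scanning the sorted pooled control values:
the one-sided derivative at t is (#positives below t - #negatives above
t) / N, which is non-decreasing.  When the minimizer is a flat interval
(always the case for perfectly separated controls) the midpoint is
returned and the interval reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ControlSet:
    """Per-well mean log10 GFP of positive and negative control wells."""

    pos_means: tuple[float, ...]
    neg_means: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.pos_means or not self.neg_means:
            raise ValueError("both control lists must be non-empty")
        vals = np.asarray(self.pos_means + self.neg_means, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("control values must be finite")

    @classmethod
    def from_summaries(
        cls, summaries, pos_label: str = "NOR00", neg_label: str = "WT"
    ) -> "ControlSet":
        """Build from retained well summaries by control strain label."""
        pos = tuple(
            s.mean_log_gfp
            for s in summaries
            if s.retained and s.strain_label == pos_label
        )
        neg = tuple(
            s.mean_log_gfp
            for s in summaries
            if s.retained and s.strain_label == neg_label
        )
        return cls(pos, neg)


@dataclass(frozen=True)
class ThresholdResult:
    """Calibrated threshold with its cost and the flat minimizing interval."""

    threshold: float  # log10 a.u.
    cost: float  # mean wrong-direction distance, log10 a.u.
    minimizing_interval: tuple[float, float]
    n_pos: int
    n_neg: int


def wrong_direction_cost(t: float, controls: ControlSet) -> float:
    """Mean distance of controls on the wrong side of threshold ``t``.

    cost(t) = [ sum_{x in neg, x > t} (x - t)
              + sum_{x in pos, x < t} (t - x) ] / (n_pos + n_neg)
    """
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    pos = np.asarray(controls.pos_means, dtype=float)
    neg = np.asarray(controls.neg_means, dtype=float)
    above = neg[neg > t] - t
    below = t - pos[pos < t]
    return float((above.sum() + below.sum()) / (pos.size + neg.size))


def optimize_threshold(controls: ControlSet) -> ThresholdResult:
    """Exact global minimizer of :func:`wrong_direction_cost`.

    The derivative only changes at control values, so the minimum is
    attained on (an interval between) breakpoints.  All breakpoints
    achieving the minimal cost are collected; the interval they span is
    flat by convexity and its midpoint is the reported threshold.
    """
    breaks = np.unique(
        np.concatenate(
            [
                np.asarray(controls.pos_means, float),
                np.asarray(controls.neg_means, float),
            ]
        )
    )
    costs = np.array([wrong_direction_cost(t, controls) for t in breaks])
    best = costs.min()
    # Flat-interval detection must tolerate rounding in the summations.
    tol = 1e-12 * max(1.0, abs(best))
    argmin = np.flatnonzero(costs <= best + tol)
    lo, hi = float(breaks[argmin[0]]), float(breaks[argmin[-1]])
    return ThresholdResult(
        threshold=(lo + hi) / 2.0,
        cost=best,
        minimizing_interval=(lo, hi),
        n_pos=len(controls.pos_means),
        n_neg=len(controls.neg_means),
    )
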