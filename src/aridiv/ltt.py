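"""Lineage-through-time curves and the null-envelope comparison.

The envelope comparison is pointwise on a regular age grid anchored at 0
(curves from different trees have incommensurate breakpoints).  "Outside"
means strictly outside the pointwise min-max range of all simulated curves;
an optional central quantile band is available but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .treeio import BranchingTimes, Chronogram, branching_times

__all__ = ["LTTCurve", "EnvelopeResult", "ltt_curve", "ltt_envelope", "envelope_compare"]


@dataclass(frozen=True)
class LTTCurve:
    """Step function age -> extant-lineage count.

    ``breakpoints`` are descending ages; ``counts[i]`` is the lineage count on
    the interval starting at ``breakpoints[i]`` (inclusive) and extending
    toward the present.  Counts start at 2 at the crown age and end at the
    tip count of the source tree.
    """

    breakpoints: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        ct = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "counts", ct)
        if len(bp) != len(ct):
            raise ValueError("breakpoints and counts must have equal length")
        if np.any(np.diff(bp) > 0):
            raise ValueError("breakpoints must be descending")
        if np.any(np.diff(ct) < 0):
            raise ValueError("counts must be non-decreasing toward the present")

    @property
    def n_tips(self) -> int:
        return int(self.counts[-1])

    @property
    def crown_age(self) -> float:
        return float(self.breakpoints[0])

    def evaluate(self, ages) -> np.ndarray:
        """Lineage count at each age: ``1 + #{breakpoints >= age}``.

        Ages older than the crown evaluate to 1 (the stem lineage).
        """
        ages = np.asarray(ages, dtype=float)
        asc = self.breakpoints[::-1]
        n_ge = len(asc) - np.searchsorted(asc, ages, side="left")
        return 1 + n_ge


def ltt_curve(source: Chronogram | BranchingTimes) -> LTTCurve:
    """LTT curve of a chronogram (or of its branching times directly)."""
    bt = source if isinstance(source, BranchingTimes) else branching_times(source)
    return LTTCurve(bt.times, np.arange(2, bt.n_tips + 1))


def ltt_envelope(trees: list) -> list[LTTCurve]:
    """One curve per tree, in input order."""
    if not trees:
        raise ValueError("envelope requires at least one tree")
    return [ltt_curve(t) for t in trees]


@dataclass(frozen=True)
class EnvelopeResult:
    """Age intervals where the empirical curve is strictly below / above
    every simulated curve (or the quantile band, in band mode)."""

    intervals_below: list[tuple[float, float]]
    intervals_above: list[tuple[float, float]]
    n_sims: int
    grid_step: float

    @property
    def outside(self) -> bool:
        return bool(self.intervals_below or self.intervals_above)

    def to_dict(self) -> dict:
        return {
            "intervals_below": [list(iv) for iv in self.intervals_below],
            "intervals_above": [list(iv) for iv in self.intervals_above],
            "n_sims": self.n_sims,
            "grid_step": self.grid_step,
        }


def _runs_to_intervals(grid: np.ndarray, flags: np.ndarray) -> list[tuple[float, float]]:
    """Merge contiguous flagged grid ages (ascending grid) into
    (older, younger) intervals sorted old -> young."""
    out = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            out.append((float(grid[j]), float(grid[i])))
            i = j + 1
        else:
            i += 1
    out.sort(key=lambda iv: -iv[0])
    return out


def envelope_compare(
    empirical: LTTCurve,
    envelope: list[LTTCurve],
    grid_step: float = 0.01,
    band: tuple[float, float] | None = None,
) -> EnvelopeResult:
    """Flag grid ages where ``empirical`` lies strictly outside all envelope
    curves.

    The grid runs from the oldest breakpoint of any input curve down to 0 in
    steps of ``grid_step`` (anchored at 0, so refining the step preserves
    verdicts at shared grid ages).  With ``band=(lo, hi)`` the comparison is
    against the pointwise lo/hi quantiles instead of the min/max extremes.
    """
    if not envelope:
        raise ValueError("envelope must be non-empty")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    top = max(c.crown_age for c in envelope + [empirical])
    grid = np.arange(0.0, top + grid_step, grid_step)
    emp = empirical.evaluate(grid)
    sims = np.vstack([c.evaluate(grid) for c in envelope])
    if band is None:
        lo = sims.min(axis=0)
        hi = sims.max(axis=0)
    else:
        lo = np.quantile(sims, band[0], axis=0)
        hi = np.quantile(sims, band[1], axis=0)
    below = emp < lo
    above = emp > hi
    return EnvelopeResult(
        intervals_below=_runs_to_intervals(grid, below),
        intervals_above=_runs_to_intervals(grid, above),
        n_sims=len(envelope),
        grid_step=float(grid_step),
    )
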