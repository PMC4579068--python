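"""Whole-clade and per-node speciation-rate estimators.

Two estimators are provided, both with natural logarithms:

* crown estimator with explicit initial lineage count:
  ``rate = (ln N - ln N0) / T``
* relative-extinction-corrected estimator:
  ``rate = ln(N (1 - eps) + eps) / T``

The two agree at ``eps = 0`` and ``N0 = 1``.  Rates are species per Myr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .treeio import Chronogram

__all__ = [
    "RateEstimate",
    "NodeRate",
    "rate_baldwin_sanderson",
    "rate_magallon_sanderson",
    "whole_clade_rate",
    "per_node_rates",
]


@dataclass(frozen=True)
class RateEstimate:
    rate: float  # species / Myr
    N: float
    N0: float | None
    T: float
    epsilon: float | None
    method: str  # "baldwin_sanderson" | "magallon_sanderson"


class NegativeRateWarning(UserWarning):
    """Log argument below 1: the estimator returns a negative rate."""


def rate_baldwin_sanderson(N: float, N0: float, T: float) -> RateEstimate:
    """``(ln N - ln N0) / T``; requires ``N >= N0 >= 1`` and ``T > 0``."""
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    if N0 < 1 or N < N0:
        raise ValueError(f"need N >= N0 >= 1, got N={N}, N0={N0}")
    rate = (np.log(N) - np.log(N0)) / T
    return RateEstimate(float(rate), N, N0, T, None, "baldwin_sanderson")


def rate_magallon_sanderson(N: float, T: float, eps: float) -> RateEstimate:
    """``ln(N (1 - eps) + eps) / T`` for relative extinction ``eps``.

    A log argument below 1 yields a negative rate; this is reported with a
    :class:`NegativeRateWarning` rather than clamped.
    """
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    if not 0 <= eps <= 1:
        raise ValueError(f"eps must lie in [0, 1], got {eps}")
    if N <= 0:
        raise ValueError(f"N must be positive, got {N}")
    arg = N * (1.0 - eps) + eps
    if arg < 1:
        warnings.warn(
            f"log argument {arg:g} < 1: negative rate reported",
            NegativeRateWarning,
            stacklevel=2,
        )
    rate = np.log(arg) / T
    return RateEstimate(float(rate), N, None, T, eps, "magallon_sanderson")


def whole_clade_rate(n_species: float, crown_age: float) -> RateEstimate:
    """Crown whole-clade speciation rate: the crown estimator with
    ``N0 = 2`` (a crown group starts from two lineages)."""
    if n_species < 2:
        raise ValueError("a crown clade has at least 2 species")
    return rate_baldwin_sanderson(n_species, 2, crown_age)


@dataclass(frozen=True)
class NodeRate:
    """One row of a per-node rate profile (old -> young order)."""

    age: float
    n_descendants: float
    clade: frozenset[str]
    estimate: RateEstimate


def per_node_rates(
    tree: Chronogram,
    eps: float = 0.0,
    total_species: int | None = None,
) -> list[NodeRate]:
    """Speciation rate at every internal node, sorted old to young.

    For each node, ``T`` is the node age and ``N`` the number of sampled
    descendant tips; with ``total_species`` given, ``N`` is scaled by
    ``total_species / n_tips`` (proportional sampling correction).  At
    ``eps = 0`` the crown estimator with ``N0 = 2`` is used, otherwise the
    relative-extinction estimator.
    """
    if not 0 <= eps <= 1:
        raise ValueError(f"eps must lie in [0, 1], got {eps}")
    scale = 1.0 if total_species is None else total_species / tree.n_tips
    rows = []
    for node in tree.internal_nodes():
        key = tree.clade_key(node)
        n = len(key) * scale
        if eps == 0:
            est = rate_baldwin_sanderson(n, 2, node.age)
        else:
            est = rate_magallon_sanderson(n, node.age, eps)
        rows.append(NodeRate(node.age, n, key, est))
    rows.sort(key=lambda r: -r.age)
    return rows
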