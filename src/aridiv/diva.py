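"""Dispersal-vicariance (DIVA) ancestral-range optimization and S-DIVA
frequency profiles over a posterior tree sample.

Cost model (canonical DIVA): a widespread ancestral range is divided at
speciation by vicariance (disjoint split into two non-empty subsets whose
union is the parent range), and a single-area ancestor speciates by
duplication (both daughters inherit the area); both events cost 0.  Along
branches each unit-area dispersal (gain) and each unit-area extinction
(loss) costs 1.
The optimization is a two-pass dynamic program over area subsets (Sankoff
style): a post-order cost table followed by a pre-order traceback that
collects, for every node, all ranges occurring in at least one globally
cost-optimal reconstruction.

Ranges are represented internally as bitmasks over the area alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .treeio import Chronogram, Node, DEFAULT_AREAS, validate_area_table

__all__ = [
    "DivaError",
    "DivaReconstruction",
    "RangeProfile",
    "NodeRangeProfile",
    "diva_reconstruct",
    "sdiva",
    "count_dispersals",
]

_INF = 10**9


class DivaError(ValueError):
    pass


def _mask_of(rng: frozenset, alphabet: tuple[str, ...]) -> int:
    m = 0
    for a in rng:
        try:
            m |= 1 << alphabet.index(a)
        except ValueError:
            raise DivaError(f"area {a!r} not in alphabet {alphabet}") from None
    return m


def _set_of(mask: int, alphabet: tuple[str, ...]) -> frozenset:
    return frozenset(a for i, a in enumerate(alphabet) if mask >> i & 1)


@lru_cache(maxsize=None)
def _popcount_table(n_areas: int) -> np.ndarray:
    return np.array([m.bit_count() for m in range(1 << n_areas)])


@lru_cache(maxsize=None)
def _splits(mask: int) -> tuple[tuple[int, int], ...]:
    """Cost-0 cladogenetic outcomes (ordered daughter start-range pairs).

    Single-area ancestor: duplication (both daughters inherit the area).
    Widespread ancestor: vicariance only (disjoint bipartitions); allowing
    free duplication out of widespread ranges would make every superset of
    an optimal range optimal too.
    """
    bits = [1 << i for i in range(mask.bit_length()) if mask >> i & 1]
    if len(bits) == 1:
        return ((mask, mask),)
    out = []
    sub = (mask - 1) & mask
    while sub > 0:
        out.append((sub, mask ^ sub))
        sub = (sub - 1) & mask
    return tuple(out)


@lru_cache(maxsize=None)
def _edgecost_table(n_areas: int) -> np.ndarray:
    """``ec[R, C1, C2]`` = cheapest dispersal+extinction cost of turning the
    daughters of a cost-0 split of ``R`` into node ranges C1 and C2."""
    size = 1 << n_areas
    pc = _popcount_table(n_areas)
    d = pc[np.bitwise_xor.outer(np.arange(size), np.arange(size))]
    ec = np.full((size, size, size), _INF, dtype=np.int64)
    for r in range(1, size):
        best = None
        for s1, s2 in _splits(r):
            c = d[s1][:, None] + d[s2][None, :]
            best = c if best is None else np.minimum(best, c)
        ec[r] = best
    ec[:, 0, :] = _INF
    ec[:, :, 0] = _INF
    return ec


@dataclass
class DivaReconstruction:
    """All cost-optimal ancestral ranges per node of one tree."""

    tree: Chronogram
    cost: int
    optimal_ranges: dict  # Node -> tuple[frozenset, ...] (internal nodes)
    multiplicity: dict  # Node -> int, = number of optimal ranges at the node
    tip_ranges: dict  # Node -> frozenset
    alphabet: tuple[str, ...]

    def by_clade(self) -> dict:
        """CladeKey -> tuple of optimal ranges, for internal nodes."""
        return {
            self.tree.clade_key(node): ranges
            for node, ranges in self.optimal_ranges.items()
        }


def diva_reconstruct(
    tree: Chronogram,
    areas: dict,
    maxareas: int | None = None,
    alphabet: tuple[str, ...] = DEFAULT_AREAS,
) -> DivaReconstruction:
    """Minimize total DIVA event cost over ancestral range assignments.

    ``maxareas`` bounds the size of ancestral ranges (default: unconstrained,
    i.e. the alphabet size).  Returns every cost-optimal range per node.
    """
    validate_area_table(areas, tree)
    m = len(alphabet)
    if maxareas is None:
        maxareas = m
    if not 1 <= maxareas <= m:
        raise DivaError(f"maxareas must lie in [1, {m}]")
    pc = _popcount_table(m)
    size = 1 << m
    admissible = (np.arange(size) > 0) & (pc <= maxareas)
    ec = _edgecost_table(m)

    tip_masks: dict[Node, int] = {}
    for tip in tree.tips():
        mask = _mask_of(areas[tip.label], alphabet)
        if pc[mask] > maxareas:
            raise DivaError(
                f"tip {tip.label!r} occupies {int(pc[mask])} areas, "
                f"exceeding maxareas={maxareas}"
            )
        tip_masks[tip] = mask

    inside: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            v = np.full(size, _INF, dtype=np.int64)
            v[tip_masks[node]] = 0
            inside[node] = v
        else:
            c1, c2 = node.children
            tmp = ec + inside[c1][None, :, None] + inside[c2][None, None, :]
            v = tmp.min(axis=(1, 2))
            v[~admissible] = _INF
            inside[node] = v

    cost = int(inside[tree.root].min())

    outside: dict[Node, np.ndarray] = {tree.root: np.where(admissible, 0, _INF)}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        c1, c2 = node.children
        ov = outside[node]
        # outside of c1: choose parent range R and sibling range C2
        t1 = ov[:, None, None] + ec + inside[c2][None, None, :]
        o1 = t1.min(axis=(0, 2))
        t2 = ov[:, None, None] + ec + inside[c1][None, :, None]
        o2 = t2.min(axis=(0, 1))
        if not c1.is_leaf:
            o1[~admissible] = _INF
        if not c2.is_leaf:
            o2[~admissible] = _INF
        outside[c1] = o1
        outside[c2] = o2

    optimal: dict[Node, tuple] = {}
    multiplicity: dict[Node, int] = {}
    for node in tree.internal_nodes():
        total = inside[node] + outside[node]
        masks = np.flatnonzero(total == cost)
        ranges = tuple(_set_of(int(k), alphabet) for k in masks)
        if not ranges:  # pragma: no cover - would indicate a DP bug
            raise DivaError("empty optimal set at an internal node")
        optimal[node] = ranges
        multiplicity[node] = len(ranges)

    return DivaReconstruction(
        tree=tree,
        cost=cost,
        optimal_ranges=optimal,
        multiplicity=multiplicity,
        tip_ranges={t: _set_of(tip_masks[t], alphabet) for t in tree.tips()},
        alphabet=alphabet,
    )


# ---------------------------------------------------------------------------
# S-DIVA


@dataclass(frozen=True)
class NodeRangeProfile:
    """Relative frequencies of alternative ancestral ranges at one clade of
    the representative tree."""

    frequencies: dict  # frozenset (range) -> float, summing to 1 if covered
    coverage: float  # fraction of sample trees containing the clade


@dataclass(frozen=True)
class RangeProfile:
    profiles: dict  # CladeKey (frozenset of tip labels) -> NodeRangeProfile
    n_trees: int


def sdiva(
    sample: list[Chronogram],
    representative: Chronogram,
    areas: dict,
    maxareas: int | None = None,
    alphabet: tuple[str, ...] = DEFAULT_AREAS,
) -> RangeProfile:
    """S-DIVA: DIVA over every sample tree, summarized per clade of the
    representative tree.

    Each sample tree containing a clade contributes weight ``1/multiplicity``
    to each of that clade's optimal ranges; frequencies are normalized over
    contributing trees only, and coverage reports the contributing fraction.
    Clades found in no sample tree get empty frequencies and coverage 0.
    """
    if not sample:
        raise DivaError("empty tree sample")
    rep_labels = frozenset(representative.tip_labels())
    for i, t in enumerate(sample):
        if frozenset(t.tip_labels()) != rep_labels:
            raise DivaError(f"sample tree {i} has a different tip label set")

    rep_keys = [
        representative.clade_key(n) for n in representative.internal_nodes()
    ]
    acc: dict[frozenset, dict] = {k: {} for k in rep_keys}
    contrib: dict[frozenset, int] = {k: 0 for k in rep_keys}

    for t in sample:
        rec = diva_reconstruct(t, areas, maxareas, alphabet)
        by_clade = rec.by_clade()
        for key in rep_keys:
            ranges = by_clade.get(key)
            if ranges is None:
                continue
            contrib[key] += 1
            w = 1.0 / len(ranges)
            bucket = acc[key]
            for rng in ranges:
                bucket[rng] = bucket.get(rng, 0.0) + w

    profiles = {}
    for key in rep_keys:
        c = contrib[key]
        freqs = (
            {rng: w / c for rng, w in acc[key].items()} if c else {}
        )
        profiles[key] = NodeRangeProfile(freqs, c / len(sample))
    return RangeProfile(profiles, len(sample))


# ---------------------------------------------------------------------------
# event accounting


def count_dispersals(
    tree: Chronogram,
    reconstruction: DivaReconstruction,
    chosen: dict,
    from_area: str,
    to_area: str,
) -> int:
    """Count parent -> child transitions in which ``to_area`` is gained by
    dispersal along the branch, out of a range containing ``from_area``.

    ``chosen`` maps each internal node to one of its optimal ranges.  For
    each node the cheapest cost-0 split consistent with the chosen child
    ranges is used (ties broken toward the numerically smallest split).
    """
    alphabet = reconstruction.alphabet
    pc = _popcount_table(len(alphabet))
    fbit = 1 << alphabet.index(from_area)
    tbit = 1 << alphabet.index(to_area)
    count = 0
    for node in tree.internal_nodes():
        if chosen[node] not in reconstruction.optimal_ranges[node]:
            raise DivaError(
                f"chosen range {set(chosen[node])} is not optimal at clade "
                f"{sorted(tree.clade_key(node))}"
            )
        r = _mask_of(chosen[node], alphabet)
        cmask = []
        for c in node.children:
            rng = reconstruction.tip_ranges[c] if c.is_leaf else chosen[c]
            cmask.append(_mask_of(rng, alphabet))
        best = min(
            _splits(r),
            key=lambda s: (
                int(pc[s[0] ^ cmask[0]] + pc[s[1] ^ cmask[1]]),
                s,
            ),
        )
        for s, c in zip(best, cmask):
            gained = c & ~s
            if gained & tbit and s & fbit:
                count += 1
    return count
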