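"""Forward birth-death tree simulation conditioned on tip count, plus random
tip pruning.

Conditioning convention
-----------------------
Simulation starts from the two crown lineages and runs forward; the clock is
stopped at the instant of the first birth event that occurs while ``n``
lineages are extant (the birth that would create lineage ``n+1``).  The tree
of the ``n`` lineages extant at that instant is returned.  Under this
convention the Yule inter-event waits while ``k`` lineages exist are
``Exp(k*lam)`` for ``k = 2..n``, so e.g. the 2-tip crown age is ``Exp(2*lam)``
and all branching times are strictly positive.

With extinction, whole simulations are retried until the stop event is
reached with the clade still alive; retries are capped.

Piecewise shift times are ages before present.  Because a forward simulation
cannot know the present before it stops, the multi-epoch simulator uses an
exact backward construction in age coordinates, which is available for
pure-birth epochs (see :func:`simulate_piecewise`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .treeio import Chronogram, Node

__all__ = [
    "SimulationSpec",
    "SimulationError",
    "simulate_yule",
    "simulate_bd",
    "simulate_piecewise",
    "prune_random_tips",
    "yule_branching_times",
]

MAX_RETRIES = 100_000


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationSpec:
    """Piecewise-constant simulation parameters.

    Epochs are listed oldest to youngest; ``shift_times`` are ages (Ma),
    strictly descending, with ``len(shift_times) == epochs - 1``.
    """

    n_tips: int
    lambdas: tuple[float, ...]
    mus: tuple[float, ...]
    shift_times: tuple[float, ...] = ()
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "lambdas", tuple(float(x) for x in self.lambdas))
        object.__setattr__(self, "mus", tuple(float(x) for x in self.mus))
        object.__setattr__(
            self, "shift_times", tuple(float(x) for x in self.shift_times)
        )
        if self.n_tips < 2:
            raise SimulationError("n_tips must be >= 2")
        if len(self.lambdas) != len(self.mus):
            raise SimulationError("lambdas and mus must have the same length")
        if len(self.shift_times) != len(self.lambdas) - 1:
            raise SimulationError("need exactly epochs - 1 shift times")
        if any(l <= 0 for l in self.lambdas):
            raise SimulationError("speciation rates must be positive")
        if any(m < 0 for m in self.mus):
            raise SimulationError("extinction rates must be non-negative")
        if any(t <= 0 for t in self.shift_times):
            raise SimulationError("shift times must be positive ages")
        if any(
            a <= b for a, b in zip(self.shift_times, self.shift_times[1:])
        ):
            raise SimulationError("shift times must be strictly descending")

    @property
    def n_epochs(self) -> int:
        return len(self.lambdas)


# ---------------------------------------------------------------------------
# forward constant-rate simulation


class _Lineage:
    __slots__ = ("node", "t_birth")

    def __init__(self, node, t_birth):
        self.node = node
        self.t_birth = t_birth


def _forward_bd_once(n, lam, mu, rng):
    """One forward pass; returns (root_segment_tree, present_time) or None on
    extinction before the stop event."""
    # segment nodes carry .t (split or death forward-time); tips get present
    root = {"t": 0.0, "children": []}
    a = {"t": None, "children": [], "parent": root}
    b = {"t": None, "children": [], "parent": root}
    root["children"] = [a, b]
    active = [a, b]
    t = 0.0
    while True:
        k = len(active)
        if k == 0:
            return None
        total = k * (lam + mu)
        t += rng.exponential(1.0 / total)
        i = int(rng.integers(k))
        if rng.random() < lam / (lam + mu):
            if k == n:
                # stopping birth: present is now; do not execute the split
                return root, t
            seg = active[i]
            seg["t"] = t
            c1 = {"t": None, "children": [], "parent": seg}
            c2 = {"t": None, "children": [], "parent": seg}
            seg["children"] = [c1, c2]
            active[i] = c1
            active.append(c2)
        else:
            seg = active[i]
            seg["t"] = t
            seg["dead"] = True
            active.pop(i)


def _reconstruct(root, present, rng) -> Chronogram:
    """Drop extinct lineages, suppress unifurcations, convert to ages."""

    def rec(seg):
        if not seg["children"]:
            if seg.get("dead"):
                return None
            return Node(None, 0.0)
        kids = [rec(c) for c in seg["children"]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node = Node(None, present - seg["t"])
        for k in kids:
            node.add_child(k)
        return node

    out = rec(root)
    if out is None or out.is_leaf:
        raise SimulationError("reconstruction yielded fewer than 2 tips")
    tree = Chronogram(out)
    _label_tips(tree)
    return tree


def _label_tips(tree: Chronogram) -> None:
    for i, tip in enumerate(tree.tips(), start=1):
        tip.label = f"t{i}"


def simulate_bd(n: int, lam: float, mu: float, seed=None) -> Chronogram:
    """Simulate a reconstructed birth-death chronogram with exactly ``n``
    extant tips (stop-at-event conditioning; see module docstring).

    ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    if n < 2:
        raise SimulationError("n must be >= 2")
    if not lam > mu:
        raise SimulationError(
            f"supercritical process required (lam={lam} <= mu={mu})"
        )
    if mu < 0:
        raise SimulationError("mu must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(MAX_RETRIES):
        res = _forward_bd_once(n, lam, mu, rng)
        if res is None:
            continue
        root, present = res
        tree = _reconstruct(root, present, rng)
        if tree.n_tips == n:
            return tree
    raise SimulationError(f"no surviving simulation in {MAX_RETRIES} attempts")


def simulate_yule(n: int, lam: float, seed=None) -> Chronogram:
    """Pure-birth special case of :func:`simulate_bd` (``mu = 0``)."""
    return simulate_bd(n, lam, 0.0, seed)


# ---------------------------------------------------------------------------
# piecewise-shift simulation (backward, exact for pure-birth epochs)


def _epoch_of(age: float, shift_times: tuple[float, ...]) -> int:
    """Epoch index (0 = oldest) containing ``age``; shift_times descending."""
    # ages >= shift_times[0] are epoch 0; < shift_times[-1] is the last epoch
    idx = len(shift_times)
    for i, s in enumerate(shift_times):
        if age >= s:
            idx = i
            break
    return idx


def _piecewise_gap(age: float, hazard_mult: int, spec: SimulationSpec, rng) -> float:
    """Draw the age increment to the next (older) branching, with hazard
    ``hazard_mult * lam(a)`` at age ``a``, starting from ``age``."""
    target = rng.exponential(1.0)
    a = age
    acc = 0.0
    while True:
        e = _epoch_of(a, spec.shift_times)
        lam = spec.lambdas[e]
        # upper bound of current epoch (older edge)
        upper = np.inf if e == 0 else spec.shift_times[e - 1]
        rate = hazard_mult * lam
        need = (target - acc) / rate
        if a + need < upper:
            return a + need - age
        acc += rate * (upper - a)
        a = upper


def _topology_from_branching_ages(ages_desc: np.ndarray, rng) -> Chronogram:
    """Uniform ranked (Yule) topology on given descending branching ages."""
    root = Node(None, float(ages_desc[0]))
    a, b = Node(None, 0.0), Node(None, 0.0)
    root.add_child(a)
    root.add_child(b)
    active = [a, b]
    for age in ages_desc[1:]:
        i = int(rng.integers(len(active)))
        tip = active[i]
        tip.age = float(age)
        c1, c2 = Node(None, 0.0), Node(None, 0.0)
        tip.add_child(c1)
        tip.add_child(c2)
        active[i] = c1
        active.append(c2)
    tree = Chronogram(root)
    _label_tips(tree)
    return tree


def simulate_piecewise(spec: SimulationSpec, seed=None) -> Chronogram:
    """Simulate a reconstructed chronogram under piecewise-constant rates
    with shift times given as ages before present.

    Single-epoch specs delegate to :func:`simulate_bd`.  Multi-epoch specs
    require pure-birth epochs (all ``mu == 0``): shift ages anchored at the
    present make a forward simulation circular (the present is only known at
    the stop event), but the pure-birth process admits an exact backward
    construction in age coordinates whose single-epoch law coincides with the
    forward stop-at-event convention.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else spec.seed
    )
    if spec.n_epochs == 1:
        return simulate_bd(spec.n_tips, spec.lambdas[0], spec.mus[0], rng)
    if any(m > 0 for m in spec.mus):
        raise NotImplementedError(
            "multi-epoch simulation with extinction is not supported: "
            "present-anchored shift ages admit an exact construction only "
            "for pure-birth epochs"
        )
    n = spec.n_tips
    ages = np.empty(n - 1)
    a = 0.0
    for j, k in enumerate(range(n, 1, -1)):
        a += _piecewise_gap(a, k, spec, rng)
        ages[j] = a
    ages = ages[::-1].copy()  # descending: crown first
    return _topology_from_branching_ages(ages, rng)


def yule_branching_times(
    n: int, lam: float, size: int, seed=None
) -> np.ndarray:
    """Vectorized branching-time sampler for constant-rate Yule trees.

    Returns a ``(size, n-1)`` array of descending ages with the same law as
    ``branching_times(simulate_yule(n, lam))`` — cumulative sums of
    independent ``Exp(k*lam)`` gaps, ``k = n..2``.  Topology is not built;
    intended for LTT-scale experiments.
    """
    if n < 2:
        raise SimulationError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ks = np.arange(n, 1, -1, dtype=float)  # n, n-1, ..., 2
    gaps = rng.exponential(1.0 / (ks * lam), size=(size, n - 1))
    ages = np.cumsum(gaps, axis=1)  # ascending: youngest .. crown
    return ages[:, ::-1]


# ---------------------------------------------------------------------------
# pruning


def prune_random_tips(tree: Chronogram, k: int, seed=None) -> Chronogram:
    """Remove ``k`` uniformly chosen tips and suppress degree-2 nodes.

    Remaining pairwise divergence ages are unchanged (node ages are carried,
    not branch lengths).  At least 2 tips must remain.
    """
    n = tree.n_tips
    if k < 0 or k > n - 2:
        raise SimulationError(
            f"cannot prune {k} of {n} tips (at least 2 must remain)"
        )
    if k == 0:
        return tree.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = sorted(tree.tip_labels())
    drop = set(rng.choice(labels, size=k, replace=False).tolist())

    out = tree.copy()

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            return None if node.label in drop else node
        kids = [rec(c) for c in node.children]
        kids = [c for c in kids if c is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node.children = []
        for c in kids:
            node.add_child(c)
        return node

    root = rec(out.root)
    assert root is not None and not root.is_leaf
    root.parent = None
    pruned = Chronogram(root, binary_strict=tree.binary_strict)
    pruned.validate()
    return pruned
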