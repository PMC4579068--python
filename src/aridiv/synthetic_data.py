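"""Truth-annotated synthetic study inputs: chronograms, random subsampling
and tip areas evolved by recorded dispersal/extinction events.

Area evolution is anagenetic only (no cladogenetic range inheritance), so
recovery tests of the range optimizer do not inherit its own assumptions;
use low event rates for such tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .bd_sim import SimulationSpec, prune_random_tips, simulate_piecewise
from .treeio import Chronogram, Node, DEFAULT_AREAS, write_newick

__all__ = [
    "Scenario",
    "SyntheticStudy",
    "zygophyllum_preset",
    "evolve_areas",
    "generate_study",
]


@dataclass(frozen=True)
class Scenario:
    """Bundle of simulation, subsampling and area-evolution parameters."""

    sim: SimulationSpec
    n_pruned: int
    area_alphabet: tuple[str, ...] = DEFAULT_AREAS
    root_range: frozenset = frozenset({"A"})
    dispersal_rate: float = 0.05  # gains / Myr / lineage
    extinction_rate: float = 0.02  # losses / Myr / lineage
    seed: int = 0

    def __post_init__(self):
        if self.n_pruned > self.sim.n_tips - 2:
            raise ValueError("cannot prune below 2 tips")
        if self.dispersal_rate < 0 or self.extinction_rate < 0:
            raise ValueError("event rates must be non-negative")
        if not self.root_range:
            raise ValueError("root range must be non-empty")
        if not self.root_range <= set(self.area_alphabet):
            raise ValueError("root range outside the area alphabet")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["root_range"] = sorted(self.root_range)
        return d


@dataclass
class SyntheticStudy:
    full_tree: Chronogram
    pruned_tree: Chronogram
    areas: dict  # tip label -> frozenset, covering the pruned tree
    true_node_ranges: dict  # CladeKey (full tree) -> frozenset
    truth: Scenario

    def manifest(self) -> dict:
        return {
            "scenario": self.truth.to_dict(),
            "full_n_tips": self.full_tree.n_tips,
            "pruned_n_tips": self.pruned_tree.n_tips,
            "full_crown_age": self.full_tree.crown_age,
            "pruned_crown_age": self.pruned_tree.crown_age,
        }

    def write(self, outdir) -> None:
        """Write full.nwk, pruned.nwk, areas.tsv, truth.json, manifest.json."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "full.nwk").write_text(write_newick(self.full_tree) + "\n")
        (out / "pruned.nwk").write_text(write_newick(self.pruned_tree) + "\n")
        lines = ["tip\tareas"]
        for label in self.pruned_tree.tip_labels():
            lines.append(f"{label}\t{''.join(sorted(self.areas[label]))}")
        (out / "areas.tsv").write_text("\n".join(lines) + "\n")
        truth = {
            "scenario": self.truth.to_dict(),
            "node_ranges": {
                ",".join(sorted(k)): sorted(v)
                for k, v in self.true_node_ranges.items()
            },
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2) + "\n"
        )


# the study-mimicking constants: a 51-species clade sampled at 23/51,
# whole-clade pure-birth rate 0.166 / Myr, 4-area alphabet, African root;
# the shifted variant switches 0.03 -> 0.32 / Myr at 10 Ma
def zygophyllum_preset(with_shift: bool = False, seed: int = 0) -> Scenario:
    if with_shift:
        sim = SimulationSpec(
            n_tips=51,
            lambdas=(0.03, 0.32),
            mus=(0.0, 0.0),
            shift_times=(10.0,),
            seed=seed,
        )
    else:
        sim = SimulationSpec(
            n_tips=51, lambdas=(0.166,), mus=(0.0,), shift_times=(), seed=seed
        )
    return Scenario(sim=sim, n_pruned=28, seed=seed)


def evolve_areas(
    tree: Chronogram,
    root_range: frozenset,
    d_rate: float,
    e_rate: float,
    seed=None,
    alphabet: tuple[str, ...] = DEFAULT_AREAS,
):
    """Evolve ranges along branches as a continuous-time process.

    Gains occur at total rate ``d_rate`` (uniform over absent areas) and
    losses at total rate ``e_rate`` (uniform over present areas, never
    emptying the range).  Returns ``(area_table, true_node_ranges)`` where
    the node ranges are keyed by CladeKey and include the root and tips.
    """
    if d_rate < 0 or e_rate < 0:
        raise ValueError("rates must be non-negative")
    if not root_range or not root_range <= set(alphabet):
        raise ValueError("invalid root range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = list(alphabet)
    node_ranges: dict[Node, frozenset] = {tree.root: frozenset(root_range)}

    def evolve_branch(state: set, duration: float) -> set:
        t = 0.0
        state = set(state)
        while True:
            absent = len(alpha) - len(state)
            can_lose = len(state) > 1
            total = d_rate * (absent > 0) + e_rate * can_lose
            if total == 0:
                return state
            t += rng.exponential(1.0 / total)
            if t >= duration:
                return state
            if rng.random() < (d_rate * (absent > 0)) / total:
                gains = sorted(set(alpha) - state)
                state.add(gains[int(rng.integers(len(gains)))])
            else:
                losses = sorted(state)
                state.remove(losses[int(rng.integers(len(losses)))])

    for node in tree.preorder():
        for child in node.children:
            res = evolve_branch(node_ranges[node], node.age - child.age)
            node_ranges[child] = frozenset(res)

    table = {t.label: node_ranges[t] for t in tree.tips()}
    by_key = {tree.clade_key(n): r for n, r in node_ranges.items()}
    return table, by_key


def generate_study(sc: Scenario) -> SyntheticStudy:
    """Compose simulation, pruning and area evolution; fully seed-driven.

    Component substreams are spawned from the scenario seed by fixed keys so
    each stage is reproducible in isolation.
    """
    ss = np.random.SeedSequence(sc.seed)
    rng_tree, rng_prune, rng_area = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    full = simulate_piecewise(sc.sim, seed=rng_tree)
    pruned = prune_random_tips(full, sc.n_pruned, seed=rng_prune)
    areas_full, node_ranges = evolve_areas(
        full,
        sc.root_range,
        sc.dispersal_rate,
        sc.extinction_rate,
        seed=rng_area,
        alphabet=sc.area_alphabet,
    )
    areas = {lab: areas_full[lab] for lab in pruned.tip_labels()}
    return SyntheticStudy(full, pruned, areas, node_ranges, sc)
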