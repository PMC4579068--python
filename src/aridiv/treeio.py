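"""Reading, validating and writing dated ultrametric trees (chronograms).

Node ages are always derived from branch lengths (root-to-tip path lengths),
never from annotation comments; ages are in Ma throughout.  Trees that are
ultrametric within a relative tolerance of ``ULTRAMETRIC_RTOL`` times the
crown age are snapped to exactly ultrametric (all tip ages reset to 0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "NewickParseError",
    "UltrametricityError",
    "Node",
    "Chronogram",
    "BranchingTimes",
    "parse_newick",
    "write_newick",
    "parse_tree_sample",
    "branching_times",
    "read_area_table",
    "DEFAULT_AREAS",
    "ULTRAMETRIC_RTOL",
]

#: default area alphabet: A=Africa, B=Asia, C=Australia, D=New World
DEFAULT_AREAS = ("A", "B", "C", "D")

#: a tree passes ultrametricity iff max tip age <= ULTRAMETRIC_RTOL * crown age
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Base class for chronogram validation errors."""


class NewickParseError(TreeError):
    """Raised when Newick/NEXUS text cannot be parsed."""


class UltrametricityError(TreeError):
    """Raised when tip ages deviate from 0 beyond tolerance."""


class Node:
    """A node of a rooted chronogram.

    Ages are in Ma before present; tips have age exactly 0.
    """

    __slots__ = ("children", "parent", "label", "age")

    def __init__(self, label: str | None = None, age: float = 0.0):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label = label
        self.age = float(age)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_leaf else "node"
        return f"<{kind} {self.label or ''} age={self.age:.4g}>"


class Chronogram:
    """Rooted, (by default) strictly binary ultrametric dated tree.

    Parameters
    ----------
    root:
        Root :class:`Node`; its age is the crown age.
    binary_strict:
        When False (trees loaded with polytomy resolution) zero-length
        internal branches are tolerated: parent ages may equal child ages.
    """

    def __init__(self, root: Node, binary_strict: bool = True):
        self.root = root
        self.binary_strict = binary_strict

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    @property
    def crown_age(self) -> float:
        return self.root.age

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    # -- clade keys ----------------------------------------------------

    def clade_key(self, node: Node) -> frozenset[str]:
        """Set of tip labels descending from ``node`` (the CladeKey)."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def clade_map(self) -> dict[frozenset[str], Node]:
        """Map CladeKey -> node for every node of the tree."""
        keys: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                keys[node] = frozenset([node.label])
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= keys[c]
                keys[node] = frozenset(acc)
        return {v: k for k, v in keys.items()}

    def copy(self) -> "Chronogram":
        def rec(n: Node) -> Node:
            m = Node(n.label, n.age)
            for c in n.children:
                m.add_child(rec(c))
            return m

        return Chronogram(rec(self.root), self.binary_strict)

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`TreeError` if any chronogram invariant fails."""
        labels = []
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("unlabeled tip encountered")
                labels.append(node.label)
                if abs(node.age) > ULTRAMETRIC_RTOL * max(self.crown_age, 1.0):
                    raise UltrametricityError(
                        f"tip {node.label!r} has nonzero age {node.age:g}"
                    )
            else:
                if len(node.children) != 2:
                    raise TreeError(
                        f"non-binary node with {len(node.children)} children "
                        "(polytomies must be resolved explicitly)"
                    )
                for c in node.children:
                    if self.binary_strict:
                        if not node.age > c.age:
                            raise TreeError(
                                f"parent age {node.age:g} not greater than "
                                f"child age {c.age:g}"
                            )
                    elif node.age < c.age - 1e-12:
                        raise TreeError(
                            f"parent age {node.age:g} below child age {c.age:g}"
                        )
        if len(set(labels)) != len(labels):
            seen, dupes = set(), set()
            for lab in labels:
                if lab in seen:
                    dupes.add(lab)
                seen.add(lab)
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        if len(labels) < 2:
            raise TreeError("a chronogram needs at least 2 tips")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Chronogram n_tips={self.n_tips} crown={self.crown_age:.4g}>"


@dataclass(frozen=True)
class BranchingTimes:
    """Descending internal-node ages; the sufficient statistic for all
    homogeneous birth-death likelihoods."""

    times: np.ndarray
    n_tips: int

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if len(t) != self.n_tips - 1:
            raise TreeError(
                f"expected {self.n_tips - 1} branching times, got {len(t)}"
            )
        if np.any(np.diff(t) > 0):
            raise TreeError("branching times must be sorted descending")
        if np.any(t < 0):
            raise TreeError("branching times must be non-negative")

    @property
    def crown_age(self) -> float:
        return float(self.times[0])


# ---------------------------------------------------------------------------
# parsing


def _from_dendropy(dtree: dendropy.Tree, resolve_polytomies: bool) -> Chronogram:
    seed = dtree.seed_node
    # collapse a degenerate unifurcating root (root-edge representation)
    while len(seed.child_nodes()) == 1:
        seed = seed.child_nodes()[0]

    # root-to-node depths from branch lengths
    depths: dict = {seed: 0.0}
    order = [seed]
    i = 0
    while i < len(order):
        nd = order[i]
        i += 1
        for ch in nd.child_nodes():
            if ch.edge.length is None:
                raise NewickParseError("branch lengths are mandatory")
            depths[ch] = depths[nd] + float(ch.edge.length)
            order.append(ch)

    leaves = [nd for nd in order if nd.is_leaf()]
    if not leaves:
        raise NewickParseError("tree has no tips")
    tip_depths = np.array([depths[nd] for nd in leaves])
    height = float(tip_depths.max())
    dev = float(height - tip_depths.min())
    if height <= 0:
        raise TreeError("tree has zero height")
    if dev > ULTRAMETRIC_RTOL * height:
        raise UltrametricityError(
            f"tree is not ultrametric: max tip-age deviation {dev:g} "
            f"exceeds tolerance {ULTRAMETRIC_RTOL * height:g}"
        )

    def label_of(nd) -> str | None:
        if nd.taxon is not None and nd.taxon.label:
            return str(nd.taxon.label)
        if nd.label:
            return str(nd.label)
        return None

    def build(nd) -> Node:
        if nd.is_leaf():
            lab = label_of(nd)
            if not lab:
                raise TreeError("unlabeled tip encountered")
            return Node(lab, 0.0)  # snap to exactly ultrametric
        node = Node(label_of(nd), max(height - depths[nd], 0.0))
        for ch in nd.child_nodes():
            node.add_child(build(ch))
        return node

    root = build(seed)
    strict = True
    if resolve_polytomies:
        strict = _resolve_polytomies(root)
    tree = Chronogram(root, binary_strict=strict)
    tree.validate()
    return tree


def _resolve_polytomies(root: Node) -> bool:
    """Resolve polytomies in place into ladders of zero-length branches.

    Returns True if the tree was already binary (strict mode kept).
    """
    strict = True
    stack = [root]
    while stack:
        node = stack.pop()
        while len(node.children) > 2:
            strict = False
            a = node.children.pop()
            b = node.children.pop()
            inner = Node(None, node.age)  # zero-length branch to parent
            inner.add_child(b)
            inner.add_child(a)
            node.add_child(inner)
        stack.extend(node.children)
    return strict


def _read_dendropy_trees(text: str) -> list[dendropy.Tree]:
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        trees = dendropy.TreeList.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise NewickParseError(f"could not parse {schema} input: {exc}") from exc
    if not trees:
        raise NewickParseError("input contains no trees")
    return list(trees)


def parse_newick(text: str, resolve_polytomies: bool = False) -> Chronogram:
    """Parse a single Newick (or NEXUS) tree into a validated Chronogram.

    Branch lengths are interpreted as durations in Myr; node ages are
    root-to-tip path lengths measured back from the present.  BEAST-style
    ``[&...]`` comments are stripped.

    Raises
    ------
    NewickParseError
        For malformed input (message includes the parser's position info).
    UltrametricityError
        When tip depths differ by more than ``1e-6 x crown age``.
    TreeError
        For other invariant violations (polytomies, duplicate labels, ...).
    """
    trees = _read_dendropy_trees(text)
    return _from_dendropy(trees[0], resolve_polytomies)


def write_newick(tree: Chronogram) -> str:
    """Serialize a Chronogram to Newick with 17-significant-digit lengths
    (lossless float round trip)."""
    buf = io.StringIO()

    def rec(node: Node):
        if node.is_leaf:
            buf.write(node.label)
        else:
            buf.write("(")
            for i, c in enumerate(node.children):
                if i:
                    buf.write(",")
                rec(c)
                buf.write(f":{node.age - c.age:.17g}")
            buf.write(")")

    rec(tree.root)
    buf.write(";")
    return buf.getvalue()


def parse_tree_sample(
    text: str, count: int | None = None, seed: int | None = None,
    resolve_polytomies: bool = False,
) -> list[Chronogram]:
    """Parse a multi-tree file and draw ``count`` trees uniformly without
    replacement (seed-reproducible).  ``count=None`` returns every tree.

    Raises ``TreeError`` if the file holds fewer trees than requested.
    """
    dtrees = _read_dendropy_trees(text)
    if count is None:
        chosen = dtrees
    else:
        if count > len(dtrees):
            raise TreeError(
                f"requested {count} trees but file contains only {len(dtrees)}"
            )
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(dtrees), size=count, replace=False)
        chosen = [dtrees[i] for i in idx]
    return [_from_dendropy(t, resolve_polytomies) for t in chosen]


def branching_times(tree: Chronogram) -> BranchingTimes:
    """Descending ages of all internal nodes (length ``n_tips - 1``)."""
    ages = sorted((n.age for n in tree.internal_nodes()), reverse=True)
    return BranchingTimes(np.array(ages), tree.n_tips)


# ---------------------------------------------------------------------------
# area tables


def read_area_table(
    text: str, alphabet: tuple[str, ...] = DEFAULT_AREAS
) -> dict[str, frozenset[str]]:
    """Parse a 2-column TSV ``tip<TAB>areas`` into tip -> AreaSet.

    The area column is a string over the alphabet (e.g. ``"AB"``).  A header
    row is skipped if its area field contains letters outside the alphabet.
    """
    table: dict[str, frozenset[str]] = {}
    alpha = set(alphabet)
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise TreeError(f"row {i + 1}: expected 2 tab-separated columns")
        label, area_str = row[0].strip(), row[1].strip()
        if i == 0 and (
            area_str.lower() in ("area", "areas", "range", "ranges")
            or (area_str and any(c.islower() for c in area_str))
        ):
            continue  # header row
        if not area_str:
            raise TreeError(f"row {i + 1} ({label!r}): empty area string")
        bad = set(area_str) - alpha
        if bad:
            raise TreeError(
                f"row {i + 1} ({label!r}): unknown area letter(s) "
                f"{''.join(sorted(bad))!r}"
            )
        if label in table:
            raise TreeError(f"row {i + 1}: duplicate tip {label!r}")
        table[label] = frozenset(area_str)
    if not table:
        raise TreeError("area table is empty")
    return table


def validate_area_table(
    table: dict[str, frozenset[str]], tree: Chronogram
) -> None:
    """Check that every tip of ``tree`` has exactly one non-empty entry."""
    missing = set(tree.tip_labels()) - set(table)
    if missing:
        raise TreeError(f"tips missing from area table: {sorted(missing)}")
    for label, rng in table.items():
        if not rng:
            raise TreeError(f"tip {label!r} has an empty range")
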