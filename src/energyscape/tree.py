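"""Disconnectivity trees: threshold lumping, funnel coloring, layout.

A disconnectivity tree hierarchically clusters the minima of a sublevel set
at uniformly spaced energy thresholds descending from a top value U_t with
spacing delta_U.  At each threshold two minima belong to the same cluster
exactly when some path connects them whose every transition state lies at
or below the threshold.  An internal node marks the last (lowest) level at
which a group of minima is still mutually connected; the barrier separating
its children therefore lies within one level spacing above the children's
split.  Leaves are individual minima drawn at their own energies.

Layouts place the tree in the plane (or in 3D): the standard layout packs
sibling subtrees into disjoint horizontal spans proportional to their leaf
counts, while the metric layout puts each leaf at its order-parameter
value(s) and each internal node at the unweighted mean of the metric values
of its descendant minima.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .database import LandscapeDatabase, SublevelSet

__all__ = [
    "EnergyLevels",
    "TreeNode",
    "DisconnectivityTree",
    "FunnelColoring",
    "GraphLayout",
    "lump_at_threshold",
    "build_tree",
    "color_funnels",
    "layout_standard",
    "layout_metric",
]

#: Neutral color for basins below the size cutoff.
NEUTRAL_COLOR = "#bfbfbf"

#: Deterministic basin palette (matplotlib "tab10" hex values), cycled.
PALETTE = ("#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
           "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf")


@dataclass(frozen=True)
class EnergyLevels:
    """Uniformly spaced thresholds descending from ``u_top``."""

    u_top: float
    delta_u: float
    n_levels: int

    def __post_init__(self):
        if self.delta_u <= 0:
            raise ValueError("delta_u must be positive")
        if self.n_levels < 1:
            raise ValueError("need at least one level")

    @property
    def levels(self) -> np.ndarray:
        return self.u_top - self.delta_u * np.arange(self.n_levels)

    @property
    def bottom(self) -> float:
        return self.u_top - self.delta_u * (self.n_levels - 1)

    @classmethod
    def from_spacing(cls, u_top: float, u_bottom: float,
                     delta_u: float) -> "EnergyLevels":
        """Levels from ``u_top`` down past ``u_bottom`` with spacing ``delta_u``."""
        if u_bottom > u_top:
            raise ValueError("u_bottom must not exceed u_top")
        n = int(np.ceil((u_top - u_bottom) / delta_u - 1e-12)) + 1
        return cls(u_top=u_top, delta_u=delta_u, n_levels=n)

    @classmethod
    def from_count(cls, u_top: float, u_bottom: float,
                   n_levels: int = 50) -> "EnergyLevels":
        """``n_levels`` levels spanning [u_bottom, u_top]."""
        if n_levels < 2:
            raise ValueError("need at least two levels to span a range")
        if u_bottom >= u_top:
            raise ValueError("u_bottom must lie below u_top")
        return cls(u_top=u_top, delta_u=(u_top - u_bottom) / (n_levels - 1),
                   n_levels=n_levels)


def lump_at_threshold(db: LandscapeDatabase, members: SublevelSet,
                      u: float):
    """Partition the members at threshold ``u``.

    Two minima share a block exactly when a path joins them whose every
    transition state lies at or below ``u`` (union-find over qualifying
    edges).  Blocks come back as a tuple of frozensets sorted by their
    smallest member index.
    """
    member_set = set(members.members)
    parent = {m: m for m in member_set}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ts in db.transition_states:
        if ts.is_self_loop() or ts.energy > u:
            continue
        if ts.i in member_set and ts.j in member_set:
            ri, rj = find(ts.i), find(ts.j)
            if ri != rj:
                parent[ri] = rj
    blocks = {}
    for m in member_set:
        blocks.setdefault(find(m), set()).add(m)
    return tuple(sorted((frozenset(b) for b in blocks.values()), key=min))


@dataclass
class TreeNode:
    """One node of a disconnectivity tree.

    Internal nodes carry the level energy at which their descendants are
    still merged; leaves carry their minimum's own energy.
    """

    node_id: int
    level_energy: float
    minima: frozenset
    children: list = field(default_factory=list)
    parent_id: Optional[int] = None
    min_index: Optional[int] = None  # set on leaves only

    @property
    def is_leaf(self) -> bool:
        return self.min_index is not None


class DisconnectivityTree:
    """Hierarchical threshold clustering of a sublevel set."""

    def __init__(self, root: TreeNode, nodes: dict, levels: EnergyLevels,
                 members: SublevelSet):
        self.root = root
        self.nodes = nodes  # node_id -> TreeNode, preorder ids
        self.levels = levels
        self.members = members

    @property
    def leaf_count(self) -> int:
        return len(self.members.members)

    def leaves(self):
        return [n for n in self.nodes.values() if n.is_leaf]

    def leaf_for(self, min_index: int) -> TreeNode:
        try:
            return self._leaf_map[min_index]
        except AttributeError:
            self._leaf_map = {n.min_index: n for n in self.leaves()}
            return self._leaf_map[min_index]

    def internal_nodes(self):
        return [n for n in self.nodes.values() if not n.is_leaf]

    def lca_level(self, i: int, j: int) -> float:
        """Level energy of the lowest common ancestor of two minima."""
        if i == j:
            return self.leaf_for(i).level_energy
        path = set()
        node = self.leaf_for(i)
        while node.parent_id is not None:
            path.add(node.parent_id)
            node = self.nodes[node.parent_id]
        node = self.leaf_for(j)
        while node.parent_id is not None:
            if node.parent_id in path:
                return self.nodes[node.parent_id].level_energy
            node = self.nodes[node.parent_id]
        raise ValueError(f"minima {i} and {j} share no ancestor")


def build_tree(db: LandscapeDatabase, members: SublevelSet,
               levels: EnergyLevels) -> DisconnectivityTree:
    """Build the disconnectivity tree of ``members`` over ``levels``.

    Clusters are computed at every level; descending, each block that
    splits becomes an internal node at the last level where it was whole.
    A block still unresolved at the bottom level becomes an internal node
    there with one leaf per remaining minimum.
    """
    level_values = levels.levels
    partitions = [lump_at_threshold(db, members, u) for u in level_values]

    nodes: dict = {}
    counter = [0]

    def new_node(level_energy, minima, min_index=None) -> TreeNode:
        node = TreeNode(node_id=counter[0], level_energy=level_energy,
                        minima=frozenset(minima), min_index=min_index)
        nodes[node.node_id] = node
        counter[0] += 1
        return node

    def sub_blocks(block, level_idx):
        return sorted((b for b in partitions[level_idx] if b <= block),
                      key=min)

    def descend(block, level_idx) -> TreeNode:
        # ``block`` is whole at level_idx; find where it resolves.
        if len(block) == 1:
            (mi,) = block
            return new_node(db.energy(mi), block, min_index=mi)
        idx = level_idx
        while idx + 1 < len(level_values):
            parts = sub_blocks(block, idx + 1)
            if len(parts) > 1:
                node = new_node(level_values[idx], block)
                for part in parts:
                    child = descend(part, idx + 1)
                    child.parent_id = node.node_id
                    node.children.append(child)
                return node
            idx += 1
        # never split: hang each minimum as a leaf from the bottom level
        node = new_node(level_values[-1], block)
        for mi in sorted(block):
            child = new_node(db.energy(mi), {mi}, min_index=mi)
            child.parent_id = node.node_id
            node.children.append(child)
        return node

    top_blocks = partitions[0]
    if len(top_blocks) == 1:
        root = descend(top_blocks[0], 0)
    else:
        # members not mutually connected below u_top: virtual root above it
        root = new_node(level_values[0] + levels.delta_u,
                        set(members.members))
        for block in top_blocks:
            child = descend(block, 0)
            child.parent_id = root.node_id
            root.children.append(child)
    tree = DisconnectivityTree(root=root, nodes=nodes, levels=levels,
                               members=members)
    tree._partitions = dict(zip(level_values.tolist(), partitions))
    return tree


# ---------------------------------------------------------------------------
# funnel coloring


@dataclass
class FunnelColoring:
    """Colors distinguishing the basins cut at a reference energy level."""

    reference_level: float
    clusters: tuple  # frozensets, descending size
    cluster_colors: tuple  # hex color per cluster, aligned
    minimum_colors: dict  # 1-based minimum index -> hex color
    node_colors: dict  # node_id -> hex color
    neutral: str = NEUTRAL_COLOR

    def distinct_colors(self):
        """Non-neutral colors, in assignment order."""
        return [c for c in self.cluster_colors if c != self.neutral]


def color_funnels(tree: DisconnectivityTree, cut_level: float,
                  min_basin_size: int = 1) -> FunnelColoring:
    """Color each basin cut at ``cut_level`` (snapped down to the level grid).

    Basins holding at least ``min_basin_size`` minima get distinct palette
    colors, assigned by descending basin size then by lowest contained
    minimum energy; smaller basins are neutral.  A tree node is colored
    when all its descendant minima share one basin.
    """
    level_values = tree.levels.levels
    eligible = level_values[level_values <= cut_level + 1e-12]
    if eligible.size == 0:
        raise ValueError(
            f"cut level {cut_level} lies below the bottom tree level "
            f"{level_values[-1]}")
    ref = float(eligible[0])
    clusters = tree._partitions[ref]
    db = tree.members.database
    order = sorted(
        clusters,
        key=lambda c: (-len(c), min(db.energy(i) for i in c), min(c)))
    colors = []
    k = 0
    for cluster in order:
        if len(cluster) >= min_basin_size:
            colors.append(PALETTE[k % len(PALETTE)])
            k += 1
        else:
            colors.append(NEUTRAL_COLOR)
    minimum_colors = {}
    for cluster, color in zip(order, colors):
        for i in cluster:
            minimum_colors[i] = color
    node_colors = {}
    for node in tree.nodes.values():
        cols = {minimum_colors[i] for i in node.minima}
        node_colors[node.node_id] = cols.pop() if len(cols) == 1 else NEUTRAL_COLOR
    return FunnelColoring(reference_level=ref, clusters=tuple(order),
                          cluster_colors=tuple(colors),
                          minimum_colors=minimum_colors,
                          node_colors=node_colors)


# ---------------------------------------------------------------------------
# layout


@dataclass
class GraphLayout:
    """Horizontal coordinates for every tree node.

    ``positions`` maps node_id to a 1- or 2-tuple; ``mode`` is
    ``"standard"`` (arbitrary units) or ``"metric"`` (order-parameter
    units, axis names in ``axis_labels``).
    """

    positions: dict
    mode: str
    axis_labels: tuple = ("",)

    @property
    def dims(self) -> int:
        return len(next(iter(self.positions.values())))


def layout_standard(tree: DisconnectivityTree) -> GraphLayout:
    """Pack sibling subtrees into disjoint spans proportional to leaf count.

    Children are ordered by (lowest descendant energy, lowest index); each
    node sits at the center of its span, so equal subtrees are mirror
    images about their parent and no two leaves coincide.
    """
    db = tree.members.database
    positions = {}

    def child_key(node: TreeNode):
        return (min(db.energy(i) for i in node.minima), min(node.minima))

    def place(node: TreeNode, x0: float, x1: float):
        positions[node.node_id] = ((x0 + x1) / 2.0,)
        if not node.children:
            return
        total = sum(len(c.minima) for c in node.children)
        x = x0
        for child in sorted(node.children, key=child_key):
            width = (x1 - x0) * len(child.minima) / total
            place(child, x, x + width)
            x += width

    place(tree.root, 0.0, 1.0)
    return GraphLayout(positions=positions, mode="standard",
                       axis_labels=("layout",))


def layout_metric(tree: DisconnectivityTree, metrics,
                  dims: Optional[int] = None) -> GraphLayout:
    """Place leaves at their metric value(s), nodes at descendant means.

    ``metrics`` is one MetricSet (1D layout) or a pair (2D layout, for 3D
    rendering).  Every member of the sublevel set must carry a value in
    each metric; each internal node's coordinate along an axis is the
    unweighted arithmetic mean of its descendant minima's values.
    """
    if hasattr(metrics, "values"):
        metrics = [metrics]
    metrics = list(metrics)
    if dims is None:
        dims = len(metrics)
    if dims != len(metrics):
        raise ValueError(f"dims={dims} but {len(metrics)} metric(s) given")
    if dims not in (1, 2):
        raise ValueError("metric layouts support 1 or 2 dimensions")
    member_list = tree.members.members
    for ms in metrics:
        missing = [i for i in member_list if i not in ms.values]
        if missing:
            raise ValueError(
                f"metric {ms.name!r} lacks values for minima {missing}")
    positions = {}
    for node in tree.nodes.values():
        positions[node.node_id] = tuple(
            float(np.mean([ms.values[i] for i in node.minima]))
            for ms in metrics)
    return GraphLayout(positions=positions, mode="metric",
                       axis_labels=tuple(ms.name for ms in metrics))
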