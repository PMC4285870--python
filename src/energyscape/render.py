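"""Static 2D/3D rendering of (metric) disconnectivity graphs.

The vertical axis is always energy (eps).  In 2D the single horizontal
axis is either an arbitrary layout coordinate or an order parameter; a 3D
graph needs a two-metric layout and is drawn as a static projection with
configurable azimuth and elevation.  Rendering is a pure consumer: it
never modifies the tree, layout or coloring, and fixed inputs plus a fixed
style give byte-identical output files.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.lines import Line2D

from .metrics import MetricSet
from .tree import DisconnectivityTree, FunnelColoring, GraphLayout

__all__ = ["RenderStyle", "render_graph"]

# stable ids inside SVG output
matplotlib.rcParams["svg.hashsalt"] = "energyscape"


@dataclass
class RenderStyle:
    """Cosmetic options for a disconnectivity-graph figure."""

    color_mode: str = "none"  # "funnel" | "order_parameter" | "none"
    colormap: str = "viridis"
    labels: tuple = ()  # minimum indices to annotate
    figsize: tuple = (7.0, 9.0)
    dpi: int = 100
    azimuth: float = -60.0
    elevation: float = 30.0
    linewidth: float = 0.8
    show_legend: bool = True

    def __post_init__(self):
        if self.color_mode not in ("funnel", "order_parameter", "none"):
            raise ValueError(
                "color_mode must be 'funnel', 'order_parameter' or 'none'")


def _node_energy(node) -> float:
    return node.level_energy


def _segment_color(node, style, coloring, order_values, cmap, vmin, vmax):
    if style.color_mode == "funnel":
        return coloring.node_colors[node.node_id]
    if style.color_mode == "order_parameter":
        vals = [order_values.values[i] for i in node.minima]
        x = (np.mean(vals) - vmin) / (vmax - vmin) if vmax > vmin else 0.5
        return cmap(float(np.clip(x, 0.0, 1.0)))
    return "black"


def render_graph(tree: DisconnectivityTree, layout: GraphLayout,
                 style: RenderStyle, dims: int, out_path,
                 coloring: FunnelColoring = None,
                 order_values: MetricSet = None) -> None:
    """Draw the tree with the given layout and write an image file.

    Every parent-child pair becomes one segment from the parent position
    at the parent's level energy to the child position at the child's
    level energy (a leaf's own energy); ``dims=3`` requires a two-metric
    layout.  The output format follows the file suffix (png/svg/pdf).
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    missing = [n for n in tree.nodes if n not in layout.positions]
    if missing:
        raise ValueError(f"layout lacks positions for nodes {missing}")
    n_coords = layout.dims
    if dims == 3 and n_coords != 2:
        raise ValueError("a 3D graph needs a layout built from two metrics")
    if dims == 2 and n_coords != 1:
        raise ValueError("a 2D graph needs a one-coordinate layout")
    if style.color_mode == "funnel" and coloring is None:
        raise ValueError("funnel coloring requested but none supplied")
    if style.color_mode == "order_parameter" and order_values is None:
        raise ValueError("order-parameter coloring requested but no metric "
                         "values supplied")
    leaf_ids = {n.min_index for n in tree.leaves()}
    bad_labels = [i for i in style.labels if i not in leaf_ids]
    if bad_labels:
        raise ValueError(f"label minima {bad_labels} are not leaves of the tree")

    cmap = matplotlib.colormaps[style.colormap]
    vmin = vmax = 0.0
    if style.color_mode == "order_parameter":
        vals = list(order_values.values.values())
        vmin, vmax = float(min(vals)), float(max(vals))

    fig = Figure(figsize=style.figsize, dpi=style.dpi)
    FigureCanvasAgg(fig)
    if dims == 3:
        ax = fig.add_subplot(projection="3d")
        ax.view_init(elev=style.elevation, azim=style.azimuth)
    else:
        ax = fig.add_subplot()

    for node in tree.nodes.values():
        if node.parent_id is None:
            continue
        parent = tree.nodes[node.parent_id]
        p0 = layout.positions[parent.node_id]
        p1 = layout.positions[node.node_id]
        color = _segment_color(node, style, coloring, order_values, cmap,
                               vmin, vmax)
        if dims == 2:
            ax.plot([p0[0], p1[0]], [_node_energy(parent), _node_energy(node)],
                    color=color, linewidth=style.linewidth,
                    solid_capstyle="round")
        else:
            ax.plot([p0[0], p1[0]], [p0[1], p1[1]],
                    [_node_energy(parent), _node_energy(node)],
                    color=color, linewidth=style.linewidth)
    if len(tree.nodes) == 1:
        # single leaf: draw a short vertical stub so the figure is not empty
        node = tree.root
        p = layout.positions[node.node_id]
        du = tree.levels.delta_u
        if dims == 2:
            ax.plot([p[0], p[0]],
                    [_node_energy(node) + du, _node_energy(node)],
                    color="black", linewidth=style.linewidth)
        else:
            ax.plot([p[0], p[0]], [p[1], p[1]],
                    [_node_energy(node) + du, _node_energy(node)],
                    color="black", linewidth=style.linewidth)

    for idx in style.labels:
        leaf = tree.leaf_for(idx)
        p = layout.positions[leaf.node_id]
        if dims == 2:
            ax.annotate(str(idx), (p[0], _node_energy(leaf)),
                        textcoords="offset points", xytext=(2, -6),
                        fontsize=8)
        else:
            ax.text(p[0], p[1], _node_energy(leaf), str(idx), fontsize=8)

    unit = " / sigma" if layout.mode == "metric" else " (arbitrary)"
    if dims == 2:
        ax.set_xlabel(layout.axis_labels[0] + unit)
        ax.set_ylabel("energy / eps")
        if layout.mode == "standard":
            ax.set_xticks([])
    else:
        ax.set_xlabel(layout.axis_labels[0] + unit)
        ax.set_ylabel(layout.axis_labels[1] + unit)
        ax.set_zlabel("energy / eps")

    if style.color_mode == "funnel" and style.show_legend:
        handles = [Line2D([0], [0], color=c, lw=2,
                          label=f"funnel {k + 1}")
                   for k, c in enumerate(coloring.distinct_colors())]
        if handles:
            ax.legend(handles=handles, loc="upper right", fontsize=8)

    suffix = str(out_path).rsplit(".", 1)[-1].lower()
    metadata = {"Date": None} if suffix == "svg" else None
    fig.savefig(out_path, metadata=metadata)
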