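"""Self-describing structured-text export of a disconnectivity graph.

One JSON document carries the tree topology, node layout coordinates,
funnel coloring and metric values, with stable key order so exports diff
cleanly and full float precision so a round trip is exact.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

from .database import LandscapeDatabase, Minimum, SublevelSet
from .metrics import MetricSet
from .tree import (DisconnectivityTree, EnergyLevels, FunnelColoring,
                   GraphLayout, TreeNode)

__all__ = ["GraphDocument", "export_graph_document", "import_graph_document"]

SCHEMA = "energyscape-graph/1"


@dataclass
class GraphDocument:
    """A re-imported graph document."""

    tree: DisconnectivityTree
    layout: Optional[GraphLayout]
    coloring: Optional[FunnelColoring]
    metrics: dict  # name -> MetricSet


def _tree_payload(tree: DisconnectivityTree) -> dict:
    nodes = []
    for node_id in sorted(tree.nodes):
        n = tree.nodes[node_id]
        nodes.append({
            "children": [c.node_id for c in n.children],
            "id": n.node_id,
            "level_energy": n.level_energy,
            "min_index": n.min_index,
            "minima": sorted(n.minima),
            "parent": n.parent_id,
        })
    return {
        "levels": {"delta_u": tree.levels.delta_u,
                   "n_levels": tree.levels.n_levels,
                   "u_top": tree.levels.u_top},
        "members": list(tree.members.members),
        "member_energies": {str(i): tree.members.database.energy(i)
                            for i in tree.members.members},
        "nodes": nodes,
        "root": tree.root.node_id,
        "threshold": tree.members.threshold,
    }


def export_graph_document(tree: DisconnectivityTree,
                          layout: Optional[GraphLayout],
                          coloring: Optional[FunnelColoring],
                          metrics, out_path) -> None:
    """Write tree + layout + coloring + metrics as one JSON document.

    ``metrics`` is an iterable of MetricSet (may be empty / None).  The
    layout and every metric must cover the tree they accompany;
    inconsistent leaf sets are rejected.
    """
    metrics = list(metrics or [])
    payload = {"schema": SCHEMA, "tree": _tree_payload(tree)}
    if layout is not None:
        missing = [n for n in tree.nodes if n not in layout.positions]
        if missing:
            raise ValueError(f"layout lacks positions for nodes {missing}")
        payload["layout"] = {
            "axis_labels": list(layout.axis_labels),
            "mode": layout.mode,
            "positions": {str(i): list(layout.positions[i])
                          for i in sorted(layout.positions)},
        }
    if coloring is not None:
        payload["coloring"] = {
            "cluster_colors": list(coloring.cluster_colors),
            "clusters": [sorted(c) for c in coloring.clusters],
            "minimum_colors": {str(i): coloring.minimum_colors[i]
                               for i in sorted(coloring.minimum_colors)},
            "neutral": coloring.neutral,
            "node_colors": {str(i): coloring.node_colors[i]
                            for i in sorted(coloring.node_colors)},
            "reference_level": coloring.reference_level,
        }
    if metrics:
        member_set = set(tree.members.members)
        for ms in metrics:
            if not member_set <= set(ms.values):
                missing = sorted(member_set - set(ms.values))
                raise ValueError(
                    f"metric {ms.name!r} lacks values for minima {missing}")
        payload["metrics"] = {
            ms.name: {"reference": None if ms.reference is None
                      else str(ms.reference),
                      "values": {str(i): ms.values[i]
                                 for i in sorted(ms.values)}}
            for ms in metrics}
    with open(out_path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def import_graph_document(path) -> GraphDocument:
    """Load a document written by :func:`export_graph_document`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema") != SCHEMA:
        raise ValueError(f"{path}: unknown schema {payload.get('schema')!r}")
    tp = payload["tree"]
    # reconstruct a minimal database holding the member energies
    energies = {int(i): e for i, e in tp["member_energies"].items()}
    minima = [Minimum(index=i, energy=energies[i]) for i in sorted(energies)]
    db = LandscapeDatabase(minima, [], metadata={"source": str(path)})
    members = SublevelSet(threshold=tp["threshold"],
                          members=tuple(tp["members"]), database=db)
    levels = EnergyLevels(u_top=tp["levels"]["u_top"],
                          delta_u=tp["levels"]["delta_u"],
                          n_levels=tp["levels"]["n_levels"])
    nodes = {}
    for spec in tp["nodes"]:
        nodes[spec["id"]] = TreeNode(
            node_id=spec["id"], level_energy=spec["level_energy"],
            minima=frozenset(spec["minima"]), parent_id=spec["parent"],
            min_index=spec["min_index"])
    for spec in tp["nodes"]:
        nodes[spec["id"]].children = [nodes[c] for c in spec["children"]]
    tree = DisconnectivityTree(root=nodes[tp["root"]], nodes=nodes,
                               levels=levels, members=members)

    layout = None
    if "layout" in payload:
        lp = payload["layout"]
        layout = GraphLayout(
            positions={int(i): tuple(v) for i, v in lp["positions"].items()},
            mode=lp["mode"], axis_labels=tuple(lp["axis_labels"]))

    coloring = None
    if "coloring" in payload:
        cp = payload["coloring"]
        coloring = FunnelColoring(
            reference_level=cp["reference_level"],
            clusters=tuple(frozenset(c) for c in cp["clusters"]),
            cluster_colors=tuple(cp["cluster_colors"]),
            minimum_colors={int(i): c for i, c in cp["minimum_colors"].items()},
            node_colors={int(i): c for i, c in cp["node_colors"].items()},
            neutral=cp["neutral"])

    metrics = {}
    for name, mp in payload.get("metrics", {}).items():
        metrics[name] = MetricSet(
            name=name, values={int(i): v for i, v in mp["values"].items()},
            reference=mp["reference"])
    return GraphDocument(tree=tree, layout=layout, coloring=coloring,
                         metrics=metrics)
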