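"""Pseudoanatomical network rendering and graph export.

Visual grammar: one node per region at its fixed layout coordinate; positive
edges black, negative edges red; stroke width proportional to |r|; node
borders colored by community membership. Difference maps draw only
significant edges, solid for gains and dashed for losses, with black/red
again carrying the sign of the CGE involved.

Rendering is deterministic: a fixed SVG hash salt and stripped date metadata
make repeated renders of identical inputs byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from matplotlib.lines import Line2D

from .community import CommunityPartition
from .compare import DifferenceMap
from .errors import MissingLayout, UnsupportedFormat
from .network import ThresholdedNetwork, write_matrix
from .registry import RegionRegistry

#: stroke widths (points) at |r| = 0 and |r| = 1
EDGE_WIDTH_MIN = 0.5
EDGE_WIDTH_MAX = 4.0

#: qualitative border palette, indexed by community label order
COMMUNITY_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)

CLASS_STYLE = {
    "gain_positive": ("black", "solid"),
    "loss_positive": ("black", "dashed"),
    "gain_negative": ("red", "solid"),
    "loss_negative": ("red", "dashed"),
    "sign_reversal": ("purple", "solid"),
}


def edge_width(r: float) -> float:
    """Linear |r| -> stroke width map (proportional, as in the figures)."""
    return EDGE_WIDTH_MIN + (EDGE_WIDTH_MAX - EDGE_WIDTH_MIN) * abs(r)


def _deterministic_save(fig, path: Path) -> None:
    with plt.rc_context({"svg.hashsalt": "cgenet"}):
        if path.suffix.lower() == ".svg":
            fig.savefig(path, format="svg", metadata={"Date": None})
        else:
            fig.savefig(path)
    plt.close(fig)


def _node_scatter(ax, registry: RegionRegistry, border_colors: dict[str, str]):
    layout = registry.layout()
    for reg in registry.regions:
        if reg.id not in layout:
            raise MissingLayout(f"no layout for {reg.id}")
        x, y = layout[reg.id]
        circle = plt.Circle(
            (x, y), 0.22, facecolor="white",
            edgecolor=border_colors.get(reg.id, "black"), linewidth=2.0,
            zorder=3,
        )
        circle.set_gid(f"node_{reg.id}")
        ax.add_patch(circle)
        ax.text(x, y, reg.id, ha="center", va="center", fontsize=5, zorder=4)


def _setup_axes(title: str):
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.set_xlim(-0.8, 9.6)
    ax.set_ylim(0.6, 10.4)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title, fontsize=9)
    return fig, ax


def render_network(
    net: ThresholdedNetwork,
    partition: CommunityPartition,
    registry: RegionRegistry,
    path: str | Path,
) -> Path:
    """Render a thresholded network in pseudoanatomical space.

    Every non-zero matrix entry becomes exactly one edge element (grouped
    under an ``edge_<a>_<b>`` id in SVG output) so renders can be audited
    against the matrix.
    """
    path = Path(path)
    layout = registry.layout()
    missing = [r for r in net.regions if r not in layout]
    if missing:
        raise MissingLayout(f"regions without layout: {missing}")
    border = {
        r: COMMUNITY_PALETTE[partition.assignment[r] % len(COMMUNITY_PALETTE)]
        for r in net.regions
    }
    fig, ax = _setup_axes(f"{net.group.label()}  (alpha={net.alpha:g}, n={net.n})")
    w = net.w
    for i, a in enumerate(net.regions):
        for b in net.regions[i + 1:]:
            r = w.at[a, b]
            if r == 0:
                continue
            (x1, y1), (x2, y2) = layout[a], layout[b]
            line = Line2D(
                [x1, x2], [y1, y2],
                color="black" if r > 0 else "red",
                linewidth=edge_width(r), zorder=1,
            )
            line.set_gid(f"edge_{min(a, b)}_{max(a, b)}")
            ax.add_line(line)
    _node_scatter(ax, registry, border)
    _deterministic_save(fig, path)
    return path


def render_difference_map(
    diff: DifferenceMap,
    registry: RegionRegistry,
    path: str | Path,
) -> Path:
    """Render only the FDR-significant classified edges of a contrast."""
    path = Path(path)
    layout = registry.layout()
    fig, ax = _setup_axes(
        f"{diff.group_a.label()} vs {diff.group_b.label()}  "
        f"(q={diff.q_level:g}, {diff.method})"
    )
    for row in diff.significant_edges.itertuples():
        # "class" is a reserved word, so itertuples mangles it; index instead
        cls = diff.edges.at[row.Index, "class"]
        style = CLASS_STYLE.get(cls)
        if style is None:
            continue  # pure strength changes carry no figure class
        color, dash = style
        (x1, y1), (x2, y2) = layout[row.region_a], layout[row.region_b]
        line = Line2D(
            [x1, x2], [y1, y2], color=color, linestyle=dash,
            linewidth=edge_width(abs(row.r_drug) or abs(row.r_base)),
            zorder=1,
        )
        a, b = sorted((row.region_a, row.region_b))
        line.set_gid(f"diffedge_{a}_{b}")
        ax.add_line(line)
    _node_scatter(ax, registry, {})
    handles = [
        Line2D([], [], color=c, linestyle=d, label=cls.replace("_", " "))
        for cls, (c, d) in CLASS_STYLE.items()
    ]
    ax.legend(handles=handles, loc="lower left", fontsize=6, frameon=False)
    _deterministic_save(fig, path)
    return path


def to_graph(
    obj: ThresholdedNetwork | DifferenceMap,
    partition: CommunityPartition | None = None,
) -> nx.Graph:
    """networkx view of a thresholded network or difference map."""
    g = nx.Graph()
    if isinstance(obj, ThresholdedNetwork):
        g.add_nodes_from(obj.regions)
        w = obj.w
        for i, a in enumerate(obj.regions):
            for b in obj.regions[i + 1:]:
                r = float(w.at[a, b])
                if r != 0:
                    g.add_edge(a, b, weight=r, sign=1 if r > 0 else -1)
        if partition is not None:
            nx.set_node_attributes(
                g, {r: int(c) for r, c in partition.assignment.items()},
                "community",
            )
    elif isinstance(obj, DifferenceMap):
        regions = sorted(
            set(obj.edges["region_a"]) | set(obj.edges["region_b"])
        )
        g.add_nodes_from(regions)
        for row in obj.significant_edges.itertuples():
            g.add_edge(
                row.region_a, row.region_b,
                weight=float(row.Z), p=float(row.p),
                q_adj=float(row.q_adj),
                cls=str(obj.edges.at[row.Index, "class"]),
            )
    else:
        raise UnsupportedFormat(f"cannot export {type(obj).__name__}")
    return g


def export_graph(
    obj: ThresholdedNetwork | DifferenceMap,
    path: str | Path,
    fmt: str = "graphml",
    partition: CommunityPartition | None = None,
) -> Path:
    """Export as GraphML, TSV edge list, or square CSV (networks only)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(to_graph(obj, partition), path)
    elif fmt == "edgelist":
        g = to_graph(obj, partition)
        rows = [
            {"region_a": min(a, b), "region_b": max(a, b), **data}
            for a, b, data in g.edges(data=True)
        ]
        rows.sort(key=lambda r: (r["region_a"], r["region_b"]))
        pd.DataFrame(
            rows, columns=["region_a", "region_b", "weight", "sign", "p",
                           "q_adj", "cls"]
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif fmt == "csv":
        if not isinstance(obj, ThresholdedNetwork):
            raise UnsupportedFormat("square CSV export is for networks only")
        write_matrix(obj.w, path)
    else:
        raise UnsupportedFormat(f"format {fmt!r} not in graphml/edgelist/csv")
    return path


def load_edgelist(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df
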