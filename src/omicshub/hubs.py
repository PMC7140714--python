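"""Set-conditioned hub analysis of a protein interaction network.

For every node of an undirected simple interaction network we count its
total partners (degree.total) and, for each query gene/protein set, the
partners belonging to that set (degree-within-set, e.g. degree.-S or
degree.NBR1-TAP). Hubs are nodes whose degree-within-set reaches a
threshold (>= 10 for the "most significant" tier, >= 3 for the annotation
tier). Two conditioned degree profiles are compared by the differential-hub
rule: flag a node when the degrees differ by at least ``abs_min`` partners
AND by at least ``rel_min`` relative to each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HubRecord",
    "DifferentialHubCall",
    "read_edge_list",
    "write_edge_list",
    "conditioned_degrees",
    "records_to_frame",
    "select_hubs",
    "annotation_tier",
    "differential_hubs",
    "expand_first_neighbors",
]


class MalformedEdgeLineError(ValueError):
    pass


@dataclass(frozen=True)
class HubRecord:
    node_id: str
    degree_total: int
    degree_in_set: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, d in self.degree_in_set.items():
            if d < 0 or d > self.degree_total:
                raise ValueError(
                    f"degree_in_set[{label!r}]={d} outside [0, degree_total="
                    f"{self.degree_total}] for node {self.node_id}"
                )


@dataclass(frozen=True)
class DifferentialHubCall:
    node_id: str
    d1: int
    d2: int
    abs_diff: int
    rel_diff: float
    flagged: bool
    direction: str  # higher-in-1 | higher-in-2 | equal


def read_edge_list(
    path, col_a: int = 0, col_b: int = 1, header: bool = True
) -> nx.Graph:
    """Read a two-column TSV edge list into an undirected simple graph.

    Extra columns (BioGRID-TAB style) are ignored; duplicate unordered pairs
    collapse to one edge; self-loops are dropped with a logged count.
    """
    g = nx.Graph()
    n_self = 0
    need = max(col_a, col_b) + 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < need:
                raise MalformedEdgeLineError(
                    f"{path}: line {lineno}: expected >= {need} columns, "
                    f"got {len(parts)}"
                )
            u, v = parts[col_a].strip(), parts[col_b].strip()
            if not u or not v:
                raise MalformedEdgeLineError(
                    f"{path}: line {lineno}: empty interactor id"
                )
            if u == v:
                n_self += 1
                continue
            g.add_edge(u, v)
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("interactor_a\tinteractor_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")


def conditioned_degrees(
    net: nx.Graph, sets: Mapping[str, Iterable[str]]
) -> list[HubRecord]:
    """Per node: total degree and degree within each labelled query set.

    Set members absent from the network contribute nothing. Output is
    ordered by node id for reproducibility.
    """
    norm = {label: set(map(str, ids)) for label, ids in sets.items()}
    records = []
    for node in sorted(net.nodes()):
        neigh = set(net.neighbors(node))
        records.append(
            HubRecord(
                node_id=node,
                degree_total=len(neigh),
                degree_in_set={
                    label: len(neigh & ids) for label, ids in norm.items()
                },
            )
        )
    return records


def records_to_frame(records: list[HubRecord]) -> pd.DataFrame:
    """Tabular view suitable for the degree-vs-degree scatter plots."""
    rows = []
    for r in records:
        row = {"node_id": r.node_id, "degree_total": r.degree_total}
        for label, d in r.degree_in_set.items():
            row[f"degree.{label}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def _degrees_for(records: list[HubRecord], set_label: str) -> dict[str, int]:
    out = {}
    for r in records:
        if set_label not in r.degree_in_set:
            raise KeyError(
                f"unknown set label {set_label!r}; available: "
                f"{sorted(r.degree_in_set)}"
            )
        out[r.node_id] = r.degree_in_set[set_label]
    return out


def select_hubs(
    records: list[HubRecord], set_label: str, min_degree: int = 10
) -> list[str]:
    """Nodes with degree-within-set >= ``min_degree`` (inclusive boundary),
    ranked by that degree descending, ties broken by node id ascending."""
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    deg = _degrees_for(records, set_label)
    hubs = [n for n, d in deg.items() if d >= min_degree]
    hubs.sort(key=lambda n: (-deg[n], n))
    return hubs


def annotation_tier(
    records: list[HubRecord], set_label: str, min_degree: int = 3
) -> list[str]:
    """Secondary tier of nodes worth annotating on the hub scatter."""
    return select_hubs(records, set_label, min_degree)


def differential_hubs(
    records1: list[HubRecord],
    records2: list[HubRecord],
    set_label: str | None = None,
    abs_min: int = 9,
    rel_min: float = 0.20,
    rel_denominator: str = "max",
) -> list[DifferentialHubCall]:
    """Compare degree-within-set between two conditioned profiles.

    A node is flagged when |d1 - d2| >= abs_min AND the relative difference
    |d1 - d2| / denom(d1, d2) >= rel_min. The denominator is max(d1, d2) by
    default (symmetric and conservative); min and mean are available.
    Nodes present in only one profile count 0 in the other.
    """
    if set_label is None:
        labels1 = {l for r in records1 for l in r.degree_in_set}
        if len(labels1) != 1:
            raise ValueError("set_label required when profiles carry several labels")
        set_label = labels1.pop()
    d1 = _degrees_for(records1, set_label) if records1 else {}
    try:
        d2 = _degrees_for(records2, set_label) if records2 else {}
    except KeyError:
        # second profile may be conditioned under a different single label
        labels2 = {l for r in records2 for l in r.degree_in_set}
        if len(labels2) == 1:
            d2 = _degrees_for(records2, labels2.pop())
        else:
            raise
    denom_fn = {
        "max": max,
        "min": min,
        "mean": lambda a, b: (a + b) / 2.0,
    }.get(rel_denominator)
    if denom_fn is None:
        raise ValueError(f"unknown rel_denominator {rel_denominator!r}")
    calls = []
    for node in sorted(set(d1) | set(d2)):
        a, b = d1.get(node, 0), d2.get(node, 0)
        abs_diff = abs(a - b)
        denom = denom_fn(a, b)
        rel_diff = 0.0 if denom == 0 else abs_diff / denom
        flagged = abs_diff >= abs_min and rel_diff >= rel_min
        direction = (
            "higher-in-1" if a > b else "higher-in-2" if b > a else "equal"
        )
        calls.append(
            DifferentialHubCall(
                node_id=node, d1=a, d2=b, abs_diff=abs_diff,
                rel_diff=rel_diff, flagged=flagged, direction=direction,
            )
        )
    return calls


def plot_degree_scatter(
    records: list[HubRecord],
    set_label: str,
    min_degree: int = 10,
    annotate_min: int = 3,
    ax=None,
):
    """Degree-within-set vs total degree scatter with the two hub tiers.

    Selected hubs (degree-within-set >= ``min_degree``) are drawn in red and
    labelled; the annotation tier (>= ``annotate_min``) in blue; the rest in
    grey. Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    xs = [r.degree_total for r in records]
    ys = [r.degree_in_set[set_label] for r in records]
    tiers = [
        "selected" if y >= min_degree else "annotated" if y >= annotate_min
        else "background"
        for y in ys
    ]
    colors = {"selected": "red", "annotated": "tab:blue", "background": "0.7"}
    for tier in ("background", "annotated", "selected"):
        pts = [(x, y) for x, y, t in zip(xs, ys, tiers) if t == tier]
        if pts:
            ax.scatter(*zip(*pts), s=12, c=colors[tier], label=tier)
    for r, t in zip(records, tiers):
        if t == "selected":
            ax.annotate(r.node_id,
                        (r.degree_total, r.degree_in_set[set_label]),
                        fontsize=7, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel("degree.total")
    ax.set_ylabel(f"degree.{set_label}")
    ax.legend(frameon=False, fontsize=8)
    return ax


def expand_first_neighbors(net: nx.Graph, seeds: Iterable[str]) -> set[str]:
    """Seeds plus every node adjacent to a seed; absent seeds pass through."""
    seeds = set(seeds)
    expanded = set(seeds)
    for s in seeds:
        if net.has_node(s):
            expanded.update(net.neighbors(s))
    return expanded
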