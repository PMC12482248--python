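"""Substructure-graph construction and inter-instance distances.

Nodes are substructure instances; edges are overlaps.  Two routes exist:

* geometric — boxes are grown by a margin of 10% of the diagonal of the
  smallest box in the image, then linked when the expanded closed
  rectangles intersect (touching counts, so substructures sharing a
  single atom are linked);
* topological — coordinate-free analogue linking instances whose atom
  sets intersect or are joined by a bond.

The distance ``d`` between two instances is the minimum number of
*intermediate* substructures on a path between them: directly linked
instances have d = 0, disconnected pairs are infinitely far apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .matching import Box, MoleculeRecord, SubstructureInstance

INFINITE = math.inf


class GraphBuildError(ValueError):
    pass


@dataclass
class SubstructureGraph:
    """Simple undirected graph over substructure instances."""

    nodes: list[SubstructureInstance]
    edges: set[tuple[int, int]]

    def __post_init__(self) -> None:
        n = len(self.nodes)
        normalized: set[tuple[int, int]] = set()
        for a, b in self.edges:
            if a == b:
                raise GraphBuildError(f"self-loop on node {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise GraphBuildError(f"edge ({a}, {b}) out of range")
            normalized.add((min(a, b), max(a, b)))
        self.edges = normalized

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_edges_from(self.edges)
        return g


def expand_boxes(
    instances: Sequence[SubstructureInstance], fraction: float = 0.10
) -> list[SubstructureInstance]:
    """Grow every box by ``fraction`` x (diagonal of the smallest box).

    The margin is computed from the smallest box *of this instance
    list* and applied uniformly, so the construction is invariant under
    translation and uniform rescaling of the layout.
    """
    if fraction < 0:
        raise GraphBuildError("fraction must be >= 0")
    if not instances:
        return []
    boxes: list[Box] = []
    for inst in instances:
        if inst.box is None:
            raise GraphBuildError("expand_boxes requires a box on every instance")
        boxes.append(inst.box)
    smallest_diag = min(
        math.hypot(x1 - x0, y1 - y0) for x0, y0, x1, y1 in boxes
    )
    margin = fraction * smallest_diag
    out = []
    for inst, (x0, y0, x1, y1) in zip(instances, boxes):
        from dataclasses import replace
        out.append(replace(
            inst, box=(x0 - margin, y0 - margin, x1 + margin, y1 + margin)
        ))
    return out


def _boxes_intersect(a: Box, b: Box) -> bool:
    # closed rectangles: touching edges or corners count as intersection
    return a[0] <= b[2] and b[0] <= a[2] and a[1] <= b[3] and b[1] <= a[3]


def build_graph_geometric(
    instances: Sequence[SubstructureInstance], fraction: float = 0.10
) -> SubstructureGraph:
    """Link instances whose expanded bounding boxes overlap."""
    expanded = expand_boxes(instances, fraction)
    edges = {
        (i, j)
        for i in range(len(expanded))
        for j in range(i + 1, len(expanded))
        if _boxes_intersect(expanded[i].box, expanded[j].box)
    }
    return SubstructureGraph(nodes=list(instances), edges=edges)


def build_graph_topological(
    instances: Sequence[SubstructureInstance], mol: MoleculeRecord
) -> SubstructureGraph:
    """Link instances sharing an atom or joined by a molecular bond."""
    for inst in instances:
        if not inst.atom_indices:
            raise GraphBuildError(
                "build_graph_topological requires atom_indices on every "
                "instance"
            )
    adjacent: set[tuple[int, int]] = set()
    for a, b, _ in mol.bonds:
        adjacent.add((min(a, b), max(a, b)))
    edges: set[tuple[int, int]] = set()
    for i in range(len(instances)):
        ai = instances[i].atom_indices
        for j in range(i + 1, len(instances)):
            aj = instances[j].atom_indices
            if ai & aj:
                edges.add((i, j))
                continue
            if any(
                (min(u, v), max(u, v)) in adjacent
                for u in ai for v in aj
            ):
                edges.add((i, j))
    return SubstructureGraph(nodes=list(instances), edges=edges)


def instance_distance(g: SubstructureGraph, a: int, b: int) -> float:
    """Minimum number of intermediate instances between ``a`` and ``b``.

    Equals (shortest-path edge count) - 1; directly linked instances are
    at distance 0; returns :data:`INFINITE` for disconnected pairs.
    Self-distance is undefined (self-pairs are excluded from the
    fingerprint sums).
    """
    n = len(g.nodes)
    if a == b:
        raise GraphBuildError("self-distance is undefined")
    if not (0 <= a < n and 0 <= b < n):
        raise GraphBuildError(f"node index out of range: ({a}, {b})")
    try:
        hops = nx.shortest_path_length(g.to_networkx(), a, b)
    except nx.NetworkXNoPath:
        return INFINITE
    return hops - 1


def all_pairs_distances(
    g: SubstructureGraph, d_max: int
) -> dict[tuple[int, int], int]:
    """Distances d <= d_max for all unordered node pairs (BFS per node)."""
    graph = g.to_networkx()
    out: dict[tuple[int, int], int] = {}
    for source in range(len(g.nodes)):
        lengths = nx.single_source_shortest_path_length(
            graph, source, cutoff=d_max + 1
        )
        for target, hops in lengths.items():
            if target <= source:
                continue
            out[(source, target)] = hops - 1
    return out
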