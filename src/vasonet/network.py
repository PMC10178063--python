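"""Data model for planar cylindrical vessel networks.

A :class:`VesselNetwork` is a graph of :class:`Node` objects (carrying a
planar position and a boundary-condition tag) joined by :class:`Segment`
objects (rigid cylinders with a radius and length).  Collinear segments may
be grouped into a named *wall* via ``wall_label``; named meeting points are
recorded in ``junction_labels``.  All quantities are SI (metres, Pa, m/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import networkx as nx
import yaml

from .errors import NetworkFileError

__all__ = [
    "BC_KINDS",
    "Node",
    "Segment",
    "FluidProperties",
    "VesselNetwork",
    "Violation",
    "validate_network",
    "split_segment_at",
    "save_network",
    "load_network",
    "export_vtk_polylines",
]

BC_KINDS = ("junction", "interior", "velocity_inlet", "pressure_outlet", "closed_end")

#: bc kinds that require a value (m/s for inlets, Pa gauge for outlets)
_VALUED_BC = {"velocity_inlet", "pressure_outlet"}

FILE_FORMAT_VERSION = 1


@dataclass
class Node:
    """A network node: planar position plus boundary-condition tag.

    ``bc_value`` is an inlet mean speed (m/s) for ``velocity_inlet`` nodes,
    a gauge pressure (Pa) for ``pressure_outlet`` nodes, and ``None``
    otherwise.
    """

    id: str
    x: float
    y: float
    bc_kind: str = "junction"
    bc_value: Optional[float] = None

    @property
    def position(self):
        return (self.x, self.y)


@dataclass
class Segment:
    """A rigid cylindrical vessel segment between two nodes."""

    id: str
    node_a: str
    node_b: str
    radius: float
    length: float
    wall_label: Optional[str] = None


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants.

    Density does not enter the steady network equations; it is retained for
    Reynolds-number diagnostics.  Defaults are whole blood.
    """

    density: float = 1060.0  # kg/m^3
    viscosity: float = 0.0035  # Pa.s

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass
class VesselNetwork:
    """Nodes + segments + named junctions.  Insertion order is meaningful:
    wall creation order (used by growth-site ranking) is the order of first
    appearance of each ``wall_label`` in ``segments``."""

    nodes: dict[str, Node] = field(default_factory=dict)
    segments: dict[str, Segment] = field(default_factory=dict)
    junction_labels: dict[str, str] = field(default_factory=dict)
    notes: str = ""

    # -- construction helpers -------------------------------------------------

    def add_node(self, id, x, y, bc_kind="junction", bc_value=None) -> Node:
        if id in self.nodes:
            raise ValueError(f"duplicate node id {id!r}")
        node = Node(id, float(x), float(y), bc_kind, bc_value)
        self.nodes[id] = node
        return node

    def add_segment(self, id, node_a, node_b, radius, wall_label=None) -> Segment:
        if id in self.segments:
            raise ValueError(f"duplicate segment id {id!r}")
        for nid in (node_a, node_b):
            if nid not in self.nodes:
                raise ValueError(f"segment {id!r} references unknown node {nid!r}")
        a, b = self.nodes[node_a], self.nodes[node_b]
        length = math.hypot(b.x - a.x, b.y - a.y)
        seg = Segment(id, node_a, node_b, float(radius), length, wall_label)
        self.segments[id] = seg
        return seg

    # -- queries --------------------------------------------------------------

    def incident_segments(self, node_id: str) -> list[Segment]:
        return [s for s in self.segments.values() if node_id in (s.node_a, s.node_b)]

    def degree(self, node_id: str) -> int:
        return len(self.incident_segments(node_id))

    def terminal_nodes(self) -> list[Node]:
        """Nodes with exactly one incident segment."""
        return [n for n in self.nodes.values() if self.degree(n.id) == 1]

    def wall_labels(self) -> list[str]:
        """Wall labels in order of first appearance."""
        seen: list[str] = []
        for seg in self.segments.values():
            if seg.wall_label is not None and seg.wall_label not in seen:
                seen.append(seg.wall_label)
        return seen

    def wall_segments(self, wall_label: str) -> list[Segment]:
        segs = [s for s in self.segments.values() if s.wall_label == wall_label]
        if not segs:
            raise KeyError(f"unknown wall label {wall_label!r}")
        return segs

    def centroid(self) -> tuple[float, float]:
        xs = [n.x for n in self.nodes.values()]
        ys = [n.y for n in self.nodes.values()]
        return (sum(xs) / len(xs), sum(ys) / len(ys))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for seg in self.segments.values():
            g.add_edge(seg.node_a, seg.node_b, segment=seg.id)
        return g

    def copy(self) -> "VesselNetwork":
        return VesselNetwork(
            nodes={k: replace(v) for k, v in self.nodes.items()},
            segments={k: replace(v) for k, v in self.segments.items()},
            junction_labels=dict(self.junction_labels),
            notes=self.notes,
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the offending node/segment id and the rule name."""

    subject: str
    rule: str
    message: str

    def __str__(self):
        return f"[{self.rule}] {self.subject}: {self.message}"


_LENGTH_RTOL = 1e-9
_DIAMETER_RANGE = (0.0001, 0.01)  # m; physiological vessel calibre window


def validate_network(network: VesselNetwork, physiological: bool = False) -> list[Violation]:
    """Check every structural invariant; return violations (possibly empty).

    Violations are data, not exceptions.  With ``physiological=True`` the
    vessel-calibre window (0.1-10 mm diameter) is also enforced.
    """
    out: list[Violation] = []

    for node in network.nodes.values():
        if node.bc_kind not in BC_KINDS:
            out.append(Violation(node.id, "bc_kind", f"unknown bc kind {node.bc_kind!r}"))
            continue
        needs_value = node.bc_kind in _VALUED_BC
        if needs_value and node.bc_value is None:
            out.append(Violation(node.id, "bc_value", f"{node.bc_kind} requires a value"))
        if not needs_value and node.bc_value is not None:
            out.append(Violation(node.id, "bc_value", f"{node.bc_kind} must not carry a value"))
        if node.bc_kind == "velocity_inlet" and node.bc_value is not None and node.bc_value <= 0:
            out.append(Violation(node.id, "inlet_speed", "inlet speed must be > 0"))
        if node.bc_kind in _VALUED_BC and network.degree(node.id) != 1:
            out.append(
                Violation(node.id, "terminal_degree",
                          f"{node.bc_kind} node must have exactly one incident segment")
            )

    seen_edges: set[frozenset] = set()
    for seg in network.segments.values():
        if seg.radius <= 0:
            out.append(Violation(seg.id, "radius", "radius must be > 0"))
        if seg.length <= 0:
            out.append(Violation(seg.id, "length", "zero-length segment"))
        a = network.nodes.get(seg.node_a)
        b = network.nodes.get(seg.node_b)
        if a is None or b is None:
            out.append(Violation(seg.id, "endpoints", "segment references unknown node"))
            continue
        dist = math.hypot(b.x - a.x, b.y - a.y)
        if seg.length > 0 and not math.isclose(seg.length, dist, rel_tol=_LENGTH_RTOL):
            out.append(
                Violation(seg.id, "length_geometry",
                          f"stored length {seg.length} != endpoint distance {dist}")
            )
        edge = frozenset((seg.node_a, seg.node_b))
        if seg.node_a == seg.node_b:
            out.append(Violation(seg.id, "self_loop", "segment joins a node to itself"))
        elif edge in seen_edges:
            out.append(Violation(seg.id, "duplicate_edge", "duplicate undirected edge"))
        seen_edges.add(edge)
        if physiological:
            d = 2 * seg.radius
            lo, hi = _DIAMETER_RANGE
            if not (lo <= d <= hi):
                out.append(
                    Violation(seg.id, "diameter_range",
                              f"diameter {d} m outside physiological window {lo}-{hi} m")
                )

    kinds = [n.bc_kind for n in network.nodes.values()]
    if "velocity_inlet" not in kinds:
        out.append(Violation("network", "no_velocity_inlet", "no velocity_inlet node"))
    if "pressure_outlet" not in kinds:
        out.append(Violation("network", "no_pressure_outlet", "no pressure_outlet node"))

    if network.nodes:
        g = network.to_graph()
        if not nx.is_connected(g):
            parts = sorted(len(c) for c in nx.connected_components(g))
            out.append(
                Violation("network", "disconnected",
                          f"graph has {len(parts)} connected components")
            )

    for name, node_id in network.junction_labels.items():
        if node_id not in network.nodes:
            out.append(Violation(name, "junction_label", f"labels unknown node {node_id!r}"))

    return out


# ---------------------------------------------------------------------------
# editing
# ---------------------------------------------------------------------------


def split_segment_at(
    network: VesselNetwork,
    segment_id: str,
    fraction: float,
    new_node_id: Optional[str] = None,
) -> tuple[VesselNetwork, str]:
    """Replace a segment by two collinear children sharing a new junction node.

    Returns ``(new_network, new_node_id)``.  Total length is conserved and
    both children inherit the parent's radius and wall label.  ``fraction``
    is measured from ``node_a``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie strictly inside (0, 1), got {fraction}")
    if segment_id not in network.segments:
        raise KeyError(f"unknown segment {segment_id!r}")

    out = network.copy()
    seg = out.segments[segment_id]
    a, b = out.nodes[seg.node_a], out.nodes[seg.node_b]
    if new_node_id is None:
        k = 1
        while f"{segment_id}.n{k}" in out.nodes:
            k += 1
        new_node_id = f"{segment_id}.n{k}"
    if new_node_id in out.nodes:
        raise ValueError(f"node id {new_node_id!r} already exists")

    mid = Node(new_node_id,
               a.x + fraction * (b.x - a.x),
               a.y + fraction * (b.y - a.y),
               "junction", None)

    child1 = Segment(f"{segment_id}.1", seg.node_a, new_node_id,
                     seg.radius, seg.length * fraction, seg.wall_label)
    child2 = Segment(f"{segment_id}.2", new_node_id, seg.node_b,
                     seg.radius, seg.length * (1 - fraction), seg.wall_label)
    for child in (child1, child2):
        if child.id in out.segments:
            raise ValueError(f"segment id {child.id!r} already exists")

    out.nodes[new_node_id] = mid
    # rebuild segment dict, keeping the children at the parent's position so
    # wall creation order is unchanged
    rebuilt: dict[str, Segment] = {}
    for sid, s in out.segments.items():
        if sid == segment_id:
            rebuilt[child1.id] = child1
            rebuilt[child2.id] = child2
        else:
            rebuilt[sid] = s
    out.segments = rebuilt
    return out, new_node_id


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _require(mapping, key, context):
    if key not in mapping:
        raise NetworkFileError(f"{context}: missing field {key!r}")
    return mapping[key]


def save_network(network: VesselNetwork, path) -> None:
    """Write a network to a structured text (YAML) file.  SI units throughout."""
    doc = {
        "format": FILE_FORMAT_VERSION,
        "units": {"length": "m", "speed": "m/s", "pressure": "Pa"},
        "notes": network.notes,
        "nodes": [
            {
                "id": n.id,
                "x": n.x,
                "y": n.y,
                "bc": n.bc_kind,
                **({"value": n.bc_value} if n.bc_value is not None else {}),
            }
            for n in network.nodes.values()
        ],
        "segments": [
            {
                "id": s.id,
                "a": s.node_a,
                "b": s.node_b,
                "radius": s.radius,
                **({"wall": s.wall_label} if s.wall_label is not None else {}),
            }
            for s in network.segments.values()
        ],
        "junctions": dict(network.junction_labels),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def load_network(path) -> VesselNetwork:
    """Read a network file written by :func:`save_network`.

    Raises :class:`NetworkFileError` naming the offending entry and field on
    malformed input.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise NetworkFileError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise NetworkFileError(f"{path}: expected a mapping at top level")
    version = _require(doc, "format", str(path))
    if version != FILE_FORMAT_VERSION:
        raise NetworkFileError(f"{path}: unsupported format version {version!r}")

    net = VesselNetwork(notes=str(doc.get("notes", "") or ""))
    for i, rec in enumerate(doc.get("nodes") or []):
        ctx = f"{path}: node {i}"
        if not isinstance(rec, dict):
            raise NetworkFileError(f"{ctx}: expected a mapping")
        nid = str(_require(rec, "id", ctx))
        bc = str(rec.get("bc", "junction"))
        value = rec.get("value")
        try:
            net.add_node(nid, float(_require(rec, "x", ctx)), float(_require(rec, "y", ctx)),
                         bc, None if value is None else float(value))
        except (TypeError, ValueError) as exc:
            raise NetworkFileError(f"{ctx}: {exc}") from exc
    for i, rec in enumerate(doc.get("segments") or []):
        ctx = f"{path}: segment {i}"
        if not isinstance(rec, dict):
            raise NetworkFileError(f"{ctx}: expected a mapping")
        try:
            net.add_segment(
                str(_require(rec, "id", ctx)),
                str(_require(rec, "a", ctx)),
                str(_require(rec, "b", ctx)),
                float(_require(rec, "radius", ctx)),
                None if rec.get("wall") is None else str(rec.get("wall")),
            )
        except (TypeError, ValueError) as exc:
            raise NetworkFileError(f"{ctx}: {exc}") from exc
    junctions = doc.get("junctions") or {}
    if not isinstance(junctions, dict):
        raise NetworkFileError(f"{path}: 'junctions' must be a mapping")
    net.junction_labels = {str(k): str(v) for k, v in junctions.items()}
    return net


def export_vtk_polylines(network: VesselNetwork, path) -> None:
    """Write the network as a legacy-ASCII VTK polyline file (visualization aid)."""
    node_index = {nid: i for i, nid in enumerate(network.nodes)}
    lines = [
        "# vtk DataFile Version 3.0",
        "vasonet vessel network",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(node_index)} double",
    ]
    for n in network.nodes.values():
        lines.append(f"{n.x} {n.y} 0.0")
    segs = list(network.segments.values())
    lines.append(f"LINES {len(segs)} {3 * len(segs)}")
    for s in segs:
        lines.append(f"2 {node_index[s.node_a]} {node_index[s.node_b]}")
    lines.append(f"CELL_DATA {len(segs)}")
    lines.append("SCALARS radius double 1")
    lines.append("LOOKUP_TABLE default")
    for s in segs:
        lines.append(str(s.radius))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
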