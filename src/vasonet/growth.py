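"""Iterative shear-driven sprouting.

Each iteration solves the network, forms the junction overlap region,
ranks walls whose binned shear meets that region, splits the selected wall
and attaches a perpendicular sprout whose free end carries the policy's
terminal boundary condition.  The loop stops at ``max_iterations``, on an
empty overlap, or when no wall qualifies; the trace records which.

Site selection among several qualifying walls is a modelling choice, not a
physical law: three explicit policies are provided and the default
(``newest_wall``) prefers the most recently created wall, which reproduces
the documented two-sprout sequence from model 1C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import PlacementError
from .network import (
    FluidProperties,
    Segment,
    VesselNetwork,
    split_segment_at,
    validate_network,
)
from .shear import (
    BinningScheme,
    OverlapResult,
    ShearInterval,
    intersect_intervals,
    junction_overlap_region,
    wall_interval,
)
from .solver import FlowSolution, assemble_and_solve

__all__ = [
    "GrowthPolicy",
    "GrowthEvent",
    "GrowthTrace",
    "find_candidate_walls",
    "sprout",
    "run_growth",
    "compare_topology",
    "infer_parent_wall",
    "write_trace",
]

SITE_POLICIES = ("newest_wall", "no_existing_junction", "closest_to_overlap_centre")


@dataclass(frozen=True)
class GrowthPolicy:
    """Parameters of the sprouting rule."""

    sprout_length: float = 0.05  # m
    sprout_radius: float = 0.001  # m
    max_iterations: int = 2
    site_selection: str = "newest_wall"
    attach_fraction: float = 0.5  # along the chosen attachment segment
    terminal_bc_kind: str = "pressure_outlet"
    terminal_bc_value: float = 0.0  # Pa gauge

    def __post_init__(self):
        if self.sprout_length <= 0 or self.sprout_radius <= 0:
            raise ValueError("sprout dimensions must be positive")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.site_selection not in SITE_POLICIES:
            raise ValueError(f"site_selection must be one of {SITE_POLICIES}")
        if not 0.0 < self.attach_fraction < 1.0:
            raise ValueError("attach_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class GrowthEvent:
    """One sprouting step."""

    iteration: int
    parent_wall: str
    attach_fraction: float  # measured along the whole parent wall
    new_wall: str
    new_segment_id: str
    new_junction: str
    overlap_used: ShearInterval


@dataclass
class GrowthTrace:
    """Full record of a growth run."""

    initial: VesselNetwork
    events: list[GrowthEvent] = field(default_factory=list)
    solutions: list[FlowSolution] = field(default_factory=list)
    overlaps: list[OverlapResult] = field(default_factory=list)
    networks: list[VesselNetwork] = field(default_factory=list)  # post-event states
    final: Optional[VesselNetwork] = None
    stopping_reason: str = ""


# ---------------------------------------------------------------------------
# candidate search
# ---------------------------------------------------------------------------


def _wall_order(network: VesselNetwork) -> dict[str, int]:
    return {w: i for i, w in enumerate(network.wall_labels())}


def _wall_has_labelled_junction(network: VesselNetwork, wall: str) -> bool:
    labelled = set(network.junction_labels.values())
    for seg in network.wall_segments(wall):
        if seg.node_a in labelled or seg.node_b in labelled:
            return True
    return False


def find_candidate_walls(solution: FlowSolution, overlap: OverlapResult,
                         scheme: BinningScheme,
                         policy: Optional[GrowthPolicy] = None):
    """Walls whose snapped shear interval meets the overlap with positive
    width and whose peak shear clears the stagnation floor, ranked by the
    site-selection policy.  Returns ``[(wall_label, qualifying_interval)]``;
    empty when the overlap is empty (growth halted, not an error)."""
    if overlap.is_empty:
        return []
    policy = policy or GrowthPolicy()
    network = solution.network
    candidates = []
    for wall in network.wall_labels():
        if max(solution.segment_shears(wall)) <= scheme.stagnation_floor:
            continue
        meet = intersect_intervals([wall_interval(solution, wall, scheme), overlap.interval])
        if meet.is_empty:
            continue
        candidates.append((wall, meet.interval))

    order = _wall_order(network)
    if policy.site_selection == "newest_wall":
        candidates.sort(key=lambda c: -order[c[0]])
    elif policy.site_selection == "no_existing_junction":
        candidates.sort(
            key=lambda c: (_wall_has_labelled_junction(network, c[0]), -order[c[0]])
        )
    else:  # closest_to_overlap_centre
        centre = overlap.interval.centre
        candidates.sort(
            key=lambda c: (abs(wall_interval(solution, c[0], scheme).centre - centre),
                           -order[c[0]])
        )
    return candidates


# ---------------------------------------------------------------------------
# sprouting
# ---------------------------------------------------------------------------


def _wall_chain(network: VesselNetwork, wall: str):
    """Segments of a wall ordered along its run, plus cumulative lengths."""
    segs = network.wall_segments(wall)
    if len(segs) == 1:
        return segs, [0.0, segs[0].length]
    counts: dict[str, int] = {}
    for s in segs:
        for nid in (s.node_a, s.node_b):
            counts[nid] = counts.get(nid, 0) + 1
    ends = [nid for nid, c in counts.items() if c == 1]
    if len(ends) != 2:
        raise PlacementError(f"wall {wall!r} is not a simple chain")
    start = min(ends, key=lambda nid: (network.nodes[nid].x, network.nodes[nid].y))
    ordered, cum = [], [0.0]
    current, remaining = start, list(segs)
    while remaining:
        nxt = next(s for s in remaining if current in (s.node_a, s.node_b))
        remaining.remove(nxt)
        ordered.append(nxt)
        cum.append(cum[-1] + nxt.length)
        current = nxt.node_b if nxt.node_a == current else nxt.node_a
    return ordered, cum


def _next_int_label(labels) -> str:
    best = 0
    for lab in labels:
        try:
            best = max(best, int(float(lab)))
        except ValueError:
            continue
    return str(best + 1)


def sprout(network: VesselNetwork, wall_label: str, fraction: float,
           policy: GrowthPolicy) -> tuple[VesselNetwork, GrowthEvent]:
    """Split ``wall_label`` at ``fraction`` of its run and grow one
    perpendicular segment there, directed away from the network centroid.

    The new attachment node becomes the next numbered junction; the sprout's
    free end carries the policy terminal boundary condition.  Raises
    :class:`PlacementError` if the sprout would coincide with an existing
    segment or the attachment lands on an existing node.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly inside (0, 1)")
    ordered, cum = _wall_chain(network, wall_label)
    total = cum[-1]
    target = fraction * total
    # locate the host segment
    seg_idx = min(
        range(len(ordered)),
        key=lambda i: 0 if cum[i] < target <= cum[i + 1] else 1,
    )
    host = ordered[seg_idx]
    local = (target - cum[seg_idx]) / host.length
    a, b = network.nodes[host.node_a], network.nodes[host.node_b]
    # orientation of the chain through the host segment
    if not 1e-9 < local < 1 - 1e-9:
        raise PlacementError(
            f"attachment at fraction {fraction} of wall {wall_label!r} lands on an existing node"
        )
    # split direction bookkeeping: _wall_chain walks node-to-node, so the host
    # may be traversed b->a; convert local fraction to the segment's own sense
    start_node = host.node_a
    chain_entry = _chain_entry_node(network, ordered, seg_idx, cum)
    if chain_entry != start_node:
        local = 1.0 - local

    grown, new_node = split_segment_at(network, host.id, local)

    # perpendicular, in-plane, away from the centroid
    ux, uy = (b.x - a.x) / host.length, (b.y - a.y) / host.length
    nx_, ny_ = -uy, ux
    cx, cy = network.centroid()
    px, py = grown.nodes[new_node].x, grown.nodes[new_node].y
    if (px - cx) * nx_ + (py - cy) * ny_ < 0:
        nx_, ny_ = -nx_, -ny_
    tip = (px + policy.sprout_length * nx_, py + policy.sprout_length * ny_)

    for node in grown.nodes.values():
        if math.isclose(node.x, tip[0], abs_tol=1e-12) and math.isclose(node.y, tip[1], abs_tol=1e-12):
            raise PlacementError("sprout tip coincides with an existing node")
    for seg in grown.segments.values():
        if _segment_overlaps(grown, seg, (px, py), tip):
            raise PlacementError(f"sprout would coincide with existing segment {seg.id!r}")

    new_wall = _next_int_label(grown.wall_labels())
    new_junction = _next_int_label(grown.junction_labels)
    tip_id = f"s{new_wall}"
    k = 1
    while tip_id in grown.nodes:
        tip_id = f"s{new_wall}.{k}"
        k += 1
    grown.add_node(tip_id, *tip,
                   bc_kind=policy.terminal_bc_kind,
                   bc_value=policy.terminal_bc_value)
    seg_id = f"{new_wall}a"
    k = 1
    while seg_id in grown.segments:
        seg_id = f"{new_wall}a.{k}"
        k += 1
    grown.segments[seg_id] = _make_sprout_segment(
        grown, seg_id, new_node, tip_id, policy.sprout_radius, new_wall
    )
    grown.junction_labels[new_junction] = new_node

    event = GrowthEvent(
        iteration=0,  # run_growth stamps the iteration and overlap
        parent_wall=wall_label,
        attach_fraction=fraction,
        new_wall=new_wall,
        new_segment_id=seg_id,
        new_junction=new_junction,
        overlap_used=ShearInterval(0.0, 1.0),
    )
    return grown, event


def _make_sprout_segment(network, seg_id, a, b, radius, wall_label):
    na, nb = network.nodes[a], network.nodes[b]
    return Segment(seg_id, a, b, radius, math.hypot(nb.x - na.x, nb.y - na.y), wall_label)


def _chain_entry_node(network, ordered, seg_idx, cum):
    """Node through which the chain walk enters segment ``seg_idx``."""
    if seg_idx == 0:
        prev_nodes = {ordered[1].node_a, ordered[1].node_b} if len(ordered) > 1 else set()
        ends = {ordered[0].node_a, ordered[0].node_b}
        shared = ends & prev_nodes
        if shared:
            (exit_node,) = shared
            (entry,) = ends - {exit_node}
            return entry
        start = min(ends, key=lambda nid: (network.nodes[nid].x, network.nodes[nid].y))
        return start
    prev = ordered[seg_idx - 1]
    ends = {ordered[seg_idx].node_a, ordered[seg_idx].node_b}
    shared = ends & {prev.node_a, prev.node_b}
    (entry,) = shared
    return entry


def _segment_overlaps(network, seg, base, tip) -> bool:
    """True if ``seg`` is collinear with and overlapping the proposed sprout."""
    a = network.nodes[seg.node_a]
    b = network.nodes[seg.node_b]
    dx, dy = tip[0] - base[0], tip[1] - base[1]
    length = math.hypot(dx, dy)
    ux, uy = dx / length, dy / length
    # reject only segments sharing the base node and running parallel
    shares_base = any(
        math.isclose(n.x, base[0], abs_tol=1e-12) and math.isclose(n.y, base[1], abs_tol=1e-12)
        for n in (a, b)
    )
    if not shares_base:
        return False
    sx, sy = (b.x - a.x) / seg.length, (b.y - a.y) / seg.length
    cross = abs(ux * sy - uy * sx)
    if cross > 1e-9:
        return False
    other = b if (math.isclose(a.x, base[0], abs_tol=1e-12)
                  and math.isclose(a.y, base[1], abs_tol=1e-12)) else a
    return (other.x - base[0]) * ux + (other.y - base[1]) * uy > 0


# ---------------------------------------------------------------------------
# the growth loop
# ---------------------------------------------------------------------------


def _select_attachment(solution: FlowSolution, wall: str, overlap: OverlapResult,
                       scheme: BinningScheme, policy: GrowthPolicy) -> float:
    """Pick the attachment point, as a fraction of the whole wall.

    Among the wall's segments whose bin meets the overlap, prefer the one
    farthest from the network centroid (ties broken toward larger x, then by
    id); attach at ``policy.attach_fraction`` of that segment.
    """
    network = solution.network
    ordered, cum = _wall_chain(network, wall)
    total = cum[-1]
    cx, cy = network.centroid()

    def qualifies(seg):
        tau = solution.wall_shear[seg.id]
        if tau <= scheme.stagnation_floor:
            return False
        bin_lo, bin_hi = scheme.bin_of(tau)
        return not intersect_intervals(
            [ShearInterval(bin_lo, bin_hi, True), overlap.interval]
        ).is_empty

    def midpoint(seg):
        a, b = network.nodes[seg.node_a], network.nodes[seg.node_b]
        return ((a.x + b.x) / 2, (a.y + b.y) / 2)

    pool = [s for s in ordered if qualifies(s)] or list(ordered)

    def rank(seg):
        mx, my = midpoint(seg)
        # quantize so symmetric layouts tie exactly and fall through to the
        # positional tie-break (larger x first)
        dist = round(math.hypot(mx - cx, my - cy), 12)
        return (-dist, -mx, seg.id)

    chosen = min(pool, key=rank)
    i = ordered.index(chosen)
    offset = cum[i] + policy.attach_fraction * chosen.length
    return offset / total


def run_growth(initial: VesselNetwork, fluid: FluidProperties,
               policy: Optional[GrowthPolicy] = None,
               scheme: Optional[BinningScheme] = None) -> GrowthTrace:
    """Iterate solve -> overlap -> candidate search -> sprout.

    Deterministic: a fixed policy and starting network always produce the
    same trace.  Solver failures mid-run are recorded in
    ``stopping_reason`` and the trace returned up to the failure.
    """
    policy = policy or GrowthPolicy()
    scheme = scheme or BinningScheme()
    trace = GrowthTrace(initial=initial.copy())
    current = initial.copy()

    for iteration in range(policy.max_iterations):
        try:
            solution = assemble_and_solve(current, fluid)
        except Exception as exc:
            trace.stopping_reason = f"error: {exc}"
            break
        overlap = junction_overlap_region(solution, scheme)
        trace.solutions.append(solution)
        trace.overlaps.append(overlap)
        if overlap.is_empty:
            trace.stopping_reason = "no overlap"
            break
        candidates = find_candidate_walls(solution, overlap, scheme, policy)
        if not candidates:
            trace.stopping_reason = "no candidates"
            break
        wall, _sub = candidates[0]
        fraction = _select_attachment(solution, wall, overlap, scheme, policy)
        grown, event = sprout(current, wall, fraction, policy)
        event = replace(event, iteration=iteration + 1, overlap_used=overlap.interval)
        bad = validate_network(grown)
        if bad:
            trace.stopping_reason = "error: sprout produced an invalid network"
            break
        current = grown
        trace.events.append(event)
        trace.networks.append(current.copy())
    else:
        trace.stopping_reason = "max_iterations"

    trace.final = current
    return trace


# ---------------------------------------------------------------------------
# regression surface
# ---------------------------------------------------------------------------


def infer_parent_wall(network: VesselNetwork, wall_label: str) -> Optional[str]:
    """The wall a given wall is attached to (via a shared node), if any."""
    own = network.wall_segments(wall_label)
    own_nodes = {n for s in own for n in (s.node_a, s.node_b)}
    for seg in network.segments.values():
        if seg.wall_label == wall_label or seg.wall_label is None:
            continue
        if seg.node_a in own_nodes or seg.node_b in own_nodes:
            return seg.wall_label
    return None


@dataclass(frozen=True)
class TopologyMatch:
    iteration: int
    walls_expected: int
    walls_actual: int
    junctions_expected: int
    junctions_actual: int
    parent_expected: Optional[str]
    parent_actual: Optional[str]

    @property
    def counts_match(self) -> bool:
        return (self.walls_expected == self.walls_actual
                and self.junctions_expected == self.junctions_actual)

    @property
    def parent_match(self) -> bool:
        return self.parent_expected == self.parent_actual


def compare_topology(trace: GrowthTrace, fixture_networks) -> list[TopologyMatch]:
    """Compare a growth trace against a sequence of expected networks,
    iteration by iteration: wall counts, junction counts and the identity of
    each sprout's parent wall (coordinates are not compared)."""
    out = []
    for i, expected in enumerate(fixture_networks):
        if i >= len(trace.networks):
            out.append(TopologyMatch(i + 1, len(expected.wall_labels()), -1,
                                     len(expected.junction_labels), -1,
                                     None, None))
            continue
        actual = trace.networks[i]
        newest_expected = expected.wall_labels()[-1]
        newest_actual = actual.wall_labels()[-1]
        out.append(TopologyMatch(
            iteration=i + 1,
            walls_expected=len(expected.wall_labels()),
            walls_actual=len(actual.wall_labels()),
            junctions_expected=len(expected.junction_labels),
            junctions_actual=len(actual.junction_labels),
            parent_expected=infer_parent_wall(expected, newest_expected),
            parent_actual=infer_parent_wall(actual, newest_actual),
        ))
    return out


def write_trace(trace: GrowthTrace, path) -> None:
    """Human-readable text log of a growth run."""
    lines = [f"initial walls: {len(trace.initial.wall_labels())}",
             f"stopping reason: {trace.stopping_reason}"]
    for i, overlap in enumerate(trace.overlaps):
        if overlap.is_empty:
            lines.append(f"iteration {i + 1}: overlap = none")
        else:
            lines.append(
                f"iteration {i + 1}: overlap = "
                f"[{overlap.interval.low:.3f}, {overlap.interval.high:.3f}] Pa "
                f"over junctions {', '.join(overlap.contributing)}"
            )
        if i < len(trace.events):
            ev = trace.events[i]
            lines.append(
                f"iteration {i + 1}: sprouted wall {ev.new_wall} from wall "
                f"{ev.parent_wall} at fraction {ev.attach_fraction:.4f} "
                f"(junction {ev.new_junction}, segment {ev.new_segment_id})"
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
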