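"""Steady reduced-order flow solution for rigid cylindrical vessel networks.

Each segment is an exact Hagen-Poiseuille resistor, ``R = 8 mu L / (pi r^4)``,
and mass is balanced at every node (the network form of incompressibility).
Velocity inlets prescribe a volumetric inflow ``Q = v pi r^2`` through their
single incident segment; pressure outlets pin the gauge pressure.  The
resulting sparse symmetric linear system in the unknown nodal pressures is
solved by direct factorization, so there is no iterative tolerance to tune;
the nodal mass residual is computed from the solution and reported, not
assumed.

Wall shear stress per segment follows the Poiseuille relation
``tau = 4 mu |Q| / (pi r^3)``, which is exact under the model's assumptions
(steady, laminar, Newtonian, rigid walls, no-slip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SolverError, ValidationFailure
from .network import FluidProperties, Segment, VesselNetwork, validate_network

__all__ = [
    "FlowSolution",
    "segment_resistance",
    "wall_shear_from_flow",
    "assemble_and_solve",
    "verify_against_analytic",
    "reynolds_number",
    "solution_table",
]


def segment_resistance(segment: Segment, fluid: FluidProperties) -> float:
    """Hydraulic resistance ``8 mu L / (pi r^4)`` in Pa.s/m^3."""
    if segment.radius <= 0 or segment.length <= 0:
        raise ValueError("segment radius and length must be positive")
    if fluid.viscosity <= 0:
        raise ValueError("viscosity must be positive")
    return 8.0 * fluid.viscosity * segment.length / (math.pi * segment.radius ** 4)


def wall_shear_from_flow(flow_rate: float, radius: float, viscosity: float) -> float:
    """Poiseuille wall shear stress ``4 mu |Q| / (pi r^3)`` in Pa."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    return 4.0 * viscosity * abs(flow_rate) / (math.pi * radius ** 3)


@dataclass
class FlowSolution:
    """Pressures, signed flows, mean velocities and wall shear for a network.

    Flows and velocities are signed positive from ``node_a`` to ``node_b``;
    wall shear uses ``|Q|`` and is non-negative.  ``residual`` is the largest
    absolute nodal mass imbalance in m^3/s.
    """

    network: VesselNetwork
    fluid: FluidProperties
    node_pressure: dict[str, float] = field(default_factory=dict)
    flow_rate: dict[str, float] = field(default_factory=dict)
    mean_velocity: dict[str, float] = field(default_factory=dict)
    wall_shear: dict[str, float] = field(default_factory=dict)
    residual: float = 0.0

    def total_inflow(self) -> float:
        """Sum of prescribed inlet flow magnitudes, m^3/s."""
        total = 0.0
        for node in self.network.nodes.values():
            if node.bc_kind == "velocity_inlet":
                seg = self.network.incident_segments(node.id)[0]
                total += abs(node.bc_value) * math.pi * seg.radius ** 2
        return total

    def segment_shears(self, wall_label: str) -> list[float]:
        return [self.wall_shear[s.id] for s in self.network.wall_segments(wall_label)]

    def incident_shears(self, node_id: str) -> list[float]:
        return [self.wall_shear[s.id] for s in self.network.incident_segments(node_id)]


def _prescribed_inflow(network: VesselNetwork, node) -> float:
    seg = network.incident_segments(node.id)[0]
    return node.bc_value * math.pi * seg.radius ** 2


def assemble_and_solve(network: VesselNetwork, fluid: FluidProperties) -> FlowSolution:
    """Solve nodal mass balance with Poiseuille segment conductances.

    Raises :class:`ValidationFailure` if the network breaks its invariants
    and :class:`SolverError` if any connected component lacks a pressure
    reference (the system would be singular).
    """
    violations = validate_network(network)
    if violations:
        raise ValidationFailure(violations)

    g = network.to_graph()
    for comp in nx.connected_components(g):
        if not any(network.nodes[n].bc_kind == "pressure_outlet" for n in comp):
            raise SolverError(
                "no pressure reference in connected component containing "
                + ", ".join(sorted(comp))
            )

    unknown = [nid for nid, n in network.nodes.items() if n.bc_kind != "pressure_outlet"]
    index = {nid: i for i, nid in enumerate(unknown)}
    n_unknown = len(unknown)

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_unknown)
    conductance: dict[str, float] = {}
    for seg in network.segments.values():
        cond = 1.0 / segment_resistance(seg, fluid)
        conductance[seg.id] = cond
        for this, other in ((seg.node_a, seg.node_b), (seg.node_b, seg.node_a)):
            if this not in index:
                continue
            i = index[this]
            rows.append(i)
            cols.append(i)
            vals.append(cond)
            if other in index:
                rows.append(i)
                cols.append(index[other])
                vals.append(-cond)
            else:  # fixed-pressure neighbour moves to the right-hand side
                rhs[i] += cond * network.nodes[other].bc_value
    for nid, node in network.nodes.items():
        if node.bc_kind == "velocity_inlet":
            rhs[index[nid]] += _prescribed_inflow(network, node)

    if n_unknown:
        matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n_unknown, n_unknown))
        try:
            pressures = spla.spsolve(matrix, rhs)
        except RuntimeError as exc:  # pragma: no cover - guarded above
            raise SolverError(f"sparse solve failed: {exc}") from exc
        if not np.all(np.isfinite(pressures)):
            raise SolverError("singular pressure system (non-finite solution)")
    else:
        pressures = np.zeros(0)

    node_pressure = {
        nid: (network.nodes[nid].bc_value
              if network.nodes[nid].bc_kind == "pressure_outlet"
              else float(pressures[index[nid]]))
        for nid in network.nodes
    }

    sol = FlowSolution(network=network, fluid=fluid, node_pressure=node_pressure)
    for seg in network.segments.values():
        q = conductance[seg.id] * (node_pressure[seg.node_a] - node_pressure[seg.node_b])
        sol.flow_rate[seg.id] = q
        sol.mean_velocity[seg.id] = q / (math.pi * seg.radius ** 2)
        sol.wall_shear[seg.id] = wall_shear_from_flow(q, seg.radius, fluid.viscosity)

    residual = 0.0
    for nid, node in network.nodes.items():
        if node.bc_kind == "pressure_outlet":
            continue
        net_out = 0.0
        for seg in network.incident_segments(nid):
            sign = 1.0 if seg.node_a == nid else -1.0
            net_out += sign * sol.flow_rate[seg.id]
        if node.bc_kind == "velocity_inlet":
            net_out -= _prescribed_inflow(network, node)
        residual = max(residual, abs(net_out))
    sol.residual = residual
    return sol


def verify_against_analytic(network: VesselNetwork, fluid: FluidProperties) -> float:
    """Relative error between solver wall shear and the analytic Poiseuille
    shear for a single straight pipe (one inlet, one outlet, uniform radius).

    Raises :class:`ValueError` if the network is not a single pipe.
    """
    inlets = [n for n in network.nodes.values() if n.bc_kind == "velocity_inlet"]
    outlets = [n for n in network.nodes.values() if n.bc_kind == "pressure_outlet"]
    if len(inlets) != 1 or len(outlets) != 1:
        raise ValueError("analytic verification requires exactly one inlet and one outlet")
    if any(network.degree(nid) > 2 for nid in network.nodes):
        raise ValueError("analytic verification requires an unbranched pipe")
    radii = {s.radius for s in network.segments.values()}
    if len(radii) != 1:
        raise ValueError("analytic verification requires a uniform radius")
    radius = radii.pop()

    q = inlets[0].bc_value * math.pi * radius ** 2
    tau_analytic = wall_shear_from_flow(q, radius, fluid.viscosity)
    solution = assemble_and_solve(network, fluid)
    tau_solver = max(solution.wall_shear.values())
    return abs(tau_solver - tau_analytic) / tau_analytic


def reynolds_number(solution: FlowSolution) -> dict[str, float]:
    """Per-segment Reynolds number ``rho |v| (2r) / mu`` (laminar diagnostic)."""
    fluid = solution.fluid
    return {
        seg.id: fluid.density * abs(solution.mean_velocity[seg.id]) * 2 * seg.radius
        / fluid.viscosity
        for seg in solution.network.segments.values()
    }


def solution_table(solution: FlowSolution) -> pd.DataFrame:
    """Flat table of the solution: one row per segment, one per node.

    Columns use SI units: flow m^3/s, velocity m/s, shear Pa, pressure Pa.
    """
    re = reynolds_number(solution)
    rows = []
    for seg in solution.network.segments.values():
        rows.append({
            "kind": "segment",
            "id": seg.id,
            "wall": seg.wall_label,
            "flow_m3_s": solution.flow_rate[seg.id],
            "velocity_m_s": solution.mean_velocity[seg.id],
            "wall_shear_Pa": solution.wall_shear[seg.id],
            "reynolds": re[seg.id],
            "pressure_Pa": None,
        })
    for nid in solution.network.nodes:
        rows.append({
            "kind": "node",
            "id": nid,
            "wall": None,
            "flow_m3_s": None,
            "velocity_m_s": None,
            "wall_shear_Pa": None,
            "reynolds": None,
            "pressure_Pa": solution.node_pressure[nid],
        })
    return pd.DataFrame(rows)
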