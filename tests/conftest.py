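"""Shared fixtures and the independent dense-solve oracle."""

import math

import numpy as np
import pytest

from vasonet import FluidProperties, VesselNetwork
from vasonet.shear import BinningScheme


@pytest.fixture
def fluid():
    return FluidProperties()  # blood: 1060 kg/m^3, 0.0035 Pa.s


@pytest.fixture
def scheme():
    return BinningScheme()  # 0.42 Pa bins, 0.42 Pa stagnation floor


@pytest.fixture
def straight_pipe():
    """Single 0.1 m pipe, r = 1 mm, 0.09 m/s inlet, 0 Pa outlet."""
    return make_pipe(velocity=0.09)


def make_pipe(velocity=0.09, radius=0.001, length=0.1):
    net = VesselNetwork()
    net.add_node("in", 0.0, 0.0, "velocity_inlet", velocity)
    net.add_node("out", length, 0.0, "pressure_outlet", 0.0)
    net.add_segment("p", "in", "out", radius, wall_label="1")
    return net


def dense_oracle_solve(network, fluid):
    """Brute-force dense nodal solve, written independently of the sparse
    solver: one row per node, Dirichlet rows for outlets, full matrix,
    ``numpy.linalg.solve``.  Returns (pressures, flows) keyed by id."""
    ids = list(network.nodes)
    pos = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    b = np.zeros(n)
    for nid in ids:
        node = network.nodes[nid]
        i = pos[nid]
        if node.bc_kind == "pressure_outlet":
            a[i, i] = 1.0
            b[i] = node.bc_value
            continue
        for seg in network.incident_segments(nid):
            g = math.pi * seg.radius ** 4 / (8.0 * fluid.viscosity * seg.length)
            other = seg.node_b if seg.node_a == nid else seg.node_a
            a[i, i] += g
            a[i, pos[other]] -= g
        if node.bc_kind == "velocity_inlet":
            seg = network.incident_segments(nid)[0]
            b[i] = node.bc_value * math.pi * seg.radius ** 2
    p = np.linalg.solve(a, b)
    pressures = {nid: float(p[pos[nid]]) for nid in ids}
    flows = {}
    for seg in network.segments.values():
        g = math.pi * seg.radius ** 4 / (8.0 * fluid.viscosity * seg.length)
        flows[seg.id] = g * (pressures[seg.node_a] - pressures[seg.node_b])
    return pressures, flows
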