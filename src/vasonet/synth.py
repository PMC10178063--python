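"""Synthetic networks and sample tables with known ground truth.

Every generator is a pure function of its spec (seed included); one named
``numpy`` generator is created per call and no global random state is
touched, so outputs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationFailure
from .network import VesselNetwork, validate_network
from .shear import RegionSampleTable, ShearInterval

__all__ = [
    "NetworkGenSpec",
    "SampleGenSpec",
    "generate_ladder_network",
    "generate_region_samples",
    "generate_random_bc_assignment",
]


@dataclass(frozen=True)
class NetworkGenSpec:
    """Parameters for a ladder-shaped branching network: two parallel trunks
    joined by ``n_sprouts`` perpendicular rungs at seeded positions."""

    n_sprouts: int
    radius: float = 0.001  # m
    trunk_length: float = 0.1  # m
    sprout_length: float = 0.05  # m
    inlet_speed: float = 0.09  # m/s
    seed: int = 0

    def __post_init__(self):
        if min(self.radius, self.trunk_length, self.sprout_length) <= 0:
            raise ValueError("all lengths and radii must be positive")
        if not 0 < self.inlet_speed <= 1.0:
            raise ValueError("inlet_speed must lie in (0, 1] m/s")
        if self.n_sprouts < 0:
            raise ValueError("n_sprouts must be non-negative")


@dataclass(frozen=True)
class SampleGenSpec:
    """Ground truth for one region's synthetic WSS samples: uniform draws
    from ``interval`` plus zero-mean Gaussian noise, truncated at zero."""

    region_label: str
    region_kind: str  # "wall" | "junction"
    interval: ShearInterval
    n_samples: int = 100
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.region_kind not in ("wall", "junction"):
            raise ValueError("region_kind must be 'wall' or 'junction'")


def generate_ladder_network(spec: NetworkGenSpec) -> VesselNetwork:
    """Two parallel trunks with perpendicular rungs at seeded positions.

    Rung x-positions are drawn once from the seed and shared by both trunks,
    so the parallel-flow solution leaves every rung stagnant.  The result
    always passes validation; degenerate specs (``n_sprouts=0`` leaves the
    trunks disconnected) raise :class:`ValidationFailure` carrying the
    report rather than returning a broken network silently.
    """
    rng = np.random.default_rng(spec.seed)
    net = VesselNetwork(notes=f"synthetic ladder (seed={spec.seed})")
    y_top, y_bot = spec.sprout_length, 0.0
    # seeded interior positions, kept away from the ends and each other
    xs = np.sort(rng.uniform(0.1, 0.9, size=spec.n_sprouts)) * spec.trunk_length
    xs = [float(x) for x in xs]

    net.add_node("tl", 0.0, y_top, "velocity_inlet", spec.inlet_speed)
    net.add_node("bl", 0.0, y_bot, "velocity_inlet", spec.inlet_speed)
    net.add_node("tr", spec.trunk_length, y_top, "pressure_outlet", 0.0)
    net.add_node("br", spec.trunk_length, y_bot, "pressure_outlet", 0.0)
    for i, x in enumerate(xs, start=1):
        net.add_node(f"jt{i}", x, y_top)
        net.add_node(f"jb{i}", x, y_bot)

    def chain(prefix, wall, left, right, y):
        ids = [left] + [f"{prefix}{i}" for i in range(1, spec.n_sprouts + 1)] + [right]
        for k, (a, b) in enumerate(zip(ids, ids[1:]), start=1):
            net.add_segment(f"{wall}.{k}", a, b, spec.radius, wall_label=wall)

    chain("jt", "1", "tl", "tr", y_top)
    chain("jb", "2", "bl", "br", y_bot)
    for i in range(1, spec.n_sprouts + 1):
        net.add_segment(f"r{i}", f"jt{i}", f"jb{i}", spec.radius, wall_label=str(2 + i))
        net.junction_labels[str(2 * i - 1)] = f"jt{i}"
        net.junction_labels[str(2 * i)] = f"jb{i}"

    violations = validate_network(net)
    if violations:
        raise ValidationFailure(violations)
    return net


def generate_region_samples(specs) -> tuple[RegionSampleTable, dict[str, ShearInterval]]:
    """Draw per-region WSS samples; returns the table and the ground truth.

    ``specs`` is an iterable of :class:`SampleGenSpec`.  Samples are uniform
    within each region's true interval plus truncated Gaussian noise — a
    synthetic-only construct (deterministic solvers have no noise model).
    """
    rows, truth = [], {}
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        iv = spec.interval
        values = rng.uniform(iv.low, iv.high, size=spec.n_samples)
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
        values = np.clip(values, 0.0, None)
        truth[spec.region_label] = iv
        rows.extend(
            {"region_label": spec.region_label,
             "region_kind": spec.region_kind,
             "wss_pa": float(v)}
            for v in values
        )
    return RegionSampleTable.from_rows(rows), truth


def generate_random_bc_assignment(network: VesselNetwork, seed: int,
                                  inlet_speed: float = 0.09) -> VesselNetwork:
    """Randomly reassign terminal nodes to inlets/outlets (at least one of
    each); deterministic under the seed."""
    terminals = network.terminal_nodes()
    if len(terminals) < 2:
        raise ValueError("need at least two terminal nodes")
    rng = np.random.default_rng(seed)
    while True:
        bits = rng.integers(0, 2, size=len(terminals))
        if 0 < bits.sum() < len(terminals):
            break
    out = network.copy()
    for node, bit in zip(terminals, bits):
        target = out.nodes[node.id]
        if bit:
            target.bc_kind = "velocity_inlet"
            target.bc_value = inlet_speed
        else:
            target.bc_kind = "pressure_outlet"
            target.bc_value = 0.0
    return out
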