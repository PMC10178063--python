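"""Builders for the ten benchmark vessel-network models (1A-1G, 2A-2C).

All models live in a plane, use 1 mm-radius rigid cylinders, 0.09 m/s
velocity inlets and 0 Pa-gauge pressure outlets.  The model-1 family is an
"H" of two horizontal trunk walls joined by a vertical connector, with
vessels added by the growth procedure; the model-2 family is the complete
ladder-with-loop network.  Inlet/outlet placements for the variants are a
best reading of the published figures and are flagged as such in each
fixture's ``notes``.

Trunk walls are 0.3 m long (see the repository decision log: shorter trunks
starve the first sprout of flow in the reduced-order model and break the
documented growth sequence); sprout walls are 0.05 m, the published length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FixtureNotFoundError
from .network import VesselNetwork

__all__ = [
    "ModelFixture",
    "build_fixture",
    "MODEL_IDS",
    "TRUNK_LENGTH",
    "SPROUT_LENGTH",
    "VESSEL_RADIUS",
    "INLET_SPEED",
]

MODEL_IDS = ("1A", "1B", "1C", "1D", "1E", "1F", "1G", "2A", "2B", "2C")

TRUNK_LENGTH = 0.3  # m
SPROUT_LENGTH = 0.05  # m, published sprout length
VESSEL_RADIUS = 0.001  # m
INLET_SPEED = 0.09  # m/s

_R = VESSEL_RADIUS
_MID = TRUNK_LENGTH / 2  # x of the vertical connector
_SEP = SPROUT_LENGTH  # vertical distance between the two trunks


@dataclass(frozen=True)
class ModelFixture:
    """A benchmark model: identifier, network, and provenance notes."""

    model_id: str
    network: VesselNetwork
    notes: str


def _model1_base() -> VesselNetwork:
    """Two horizontal trunks (walls 1, 3) joined mid-span by a vertical
    connector (wall 2).  Terminals are left untagged; callers assign BCs."""
    net = VesselNetwork()
    net.add_node("tl", 0.0, _SEP)
    net.add_node("j1", _MID, _SEP)
    net.add_node("tr", TRUNK_LENGTH, _SEP)
    net.add_node("bl", 0.0, 0.0)
    net.add_node("j2", _MID, 0.0)
    net.add_node("br", TRUNK_LENGTH, 0.0)
    net.add_segment("1a", "tl", "j1", _R, wall_label="1")
    net.add_segment("1b", "j1", "tr", _R, wall_label="1")
    net.add_segment("2a", "j1", "j2", _R, wall_label="2")
    net.add_segment("3a", "bl", "j2", _R, wall_label="3")
    net.add_segment("3b", "j2", "br", _R, wall_label="3")
    net.junction_labels = {"1": "j1", "2": "j2"}
    return net


def _set_bc(net: VesselNetwork, inlets=(), outlets=(), closed=()):
    for nid in inlets:
        net.nodes[nid].bc_kind = "velocity_inlet"
        net.nodes[nid].bc_value = INLET_SPEED
    for nid in outlets:
        net.nodes[nid].bc_kind = "pressure_outlet"
        net.nodes[nid].bc_value = 0.0
    for nid in closed:
        net.nodes[nid].bc_kind = "closed_end"
        net.nodes[nid].bc_value = None


def _add_sprout_4(net: VesselNetwork) -> None:
    """First sprout: wall 4 descends from the right half of trunk wall 3."""
    x4 = (_MID + TRUNK_LENGTH) / 2
    net.add_node("j3", x4, 0.0)
    net.add_node("s4", x4, -SPROUT_LENGTH)
    # re-split wall 3's right half at the attachment point
    del net.segments["3b"]
    net.add_segment("3b1", "j2", "j3", _R, wall_label="3")
    net.add_segment("3b2", "j3", "br", _R, wall_label="3")
    net.add_segment("4a", "j3", "s4", _R, wall_label="4")
    net.junction_labels["3"] = "j3"


def _add_sprout_5(net: VesselNetwork) -> None:
    """Second sprout: wall 5 runs rightward from the midpoint of wall 4."""
    x4 = (_MID + TRUNK_LENGTH) / 2
    y5 = -SPROUT_LENGTH / 2
    net.add_node("j4", x4, y5)
    net.add_node("s5", x4 + SPROUT_LENGTH, y5)
    del net.segments["4a"]
    net.add_segment("4a1", "j3", "j4", _R, wall_label="4")
    net.add_segment("4a2", "j4", "s4", _R, wall_label="4")
    net.add_segment("5a", "j4", "s5", _R, wall_label="5")
    net.junction_labels["4"] = "j4"


def _model2_base(angled_connector: bool = False) -> VesselNetwork:
    """The complete network: trunks, vertical connector, a descending branch
    (wall 4), a lower horizontal branch (wall 5) and a return branch (wall 6)
    closing a loop back onto the lower trunk."""
    net = VesselNetwork()
    x2 = _MID + 0.02 if angled_connector else _MID  # connector foot
    x6 = _MID + 0.025  # wall-6 attachment on trunk 3
    x4 = (_MID + TRUNK_LENGTH) / 2  # wall-4 attachment on trunk 3
    y5 = -SPROUT_LENGTH  # lower branch elevation

    net.add_node("tl", 0.0, _SEP)
    net.add_node("j1", _MID, _SEP)
    net.add_node("tr", TRUNK_LENGTH, _SEP)
    net.add_node("bl", 0.0, 0.0)
    net.add_node("j2", x2, 0.0)
    net.add_node("j6", x6, 0.0)
    net.add_node("j3", x4, 0.0)
    net.add_node("br", TRUNK_LENGTH, 0.0)
    net.add_node("j4", x4, y5)
    net.add_node("j5", x6, y5)
    net.add_node("s5", x4 + SPROUT_LENGTH, y5)

    net.add_segment("1a", "tl", "j1", _R, wall_label="1")
    net.add_segment("1b", "j1", "tr", _R, wall_label="1")
    net.add_segment("2a", "j1", "j2", _R, wall_label="2")
    bottom = sorted([("j2", x2), ("j6", x6), ("j3", x4)], key=lambda t: t[1])
    chain = [("bl", 0.0)] + bottom + [("br", TRUNK_LENGTH)]
    for i, ((a, _), (b, _)) in enumerate(zip(chain, chain[1:])):
        net.add_segment(f"3{'abcd'[i]}", a, b, _R, wall_label="3")
    net.add_segment("4a", "j3", "j4", _R, wall_label="4")
    net.add_segment("5a", "j5", "j4", _R, wall_label="5")
    net.add_segment("5b", "j4", "s5", _R, wall_label="5")
    net.add_segment("6a", "j6", "j5", _R, wall_label="6")
    net.junction_labels = {"1": "j1", "2": "j2", "3": "j3", "4": "j4", "5": "j5", "6": "j6"}
    return net


def build_fixture(model_id: str) -> ModelFixture:
    """Build one of the ten benchmark models.  Deterministic: no randomness.

    Raises :class:`FixtureNotFoundError` for unknown identifiers.
    """
    mid = str(model_id).upper()
    if mid not in MODEL_IDS:
        raise FixtureNotFoundError(
            f"unknown model id {model_id!r}; expected one of {', '.join(MODEL_IDS)}"
        )

    figure_note = ("inlet/outlet placement read from the published figures; "
                   "the text reports outcomes, not coordinates")

    if mid in ("1A", "1B", "1C"):
        net = _model1_base()
        if mid == "1A":
            # antiparallel trunk flow: the connector sees equal mid-span
            # pressures and stagnates
            _set_bc(net, inlets=("tl", "br"), outlets=("tr", "bl"))
            notes = f"H network, antiparallel trunk flow ({figure_note})"
        elif mid == "1B":
            # both upper terminals feed in; flow converges through the
            # connector, overloading walls 1 and 2
            _set_bc(net, inlets=("tl", "tr"), outlets=("bl", "br"))
            notes = (f"H network, converging upper-trunk inflow; whether the second "
                     f"inlet also ran at 0.09 m/s is unreported and assumed here "
                     f"({figure_note})")
        else:
            # parallel left-to-right flow in both trunks; stagnant connector
            _set_bc(net, inlets=("tl", "bl"), outlets=("tr", "br"))
            notes = f"H network, parallel trunk flow; baseline for growth ({figure_note})"
        return ModelFixture(mid, net, notes)

    if mid in ("1D", "1F"):
        net = _model1_base()
        _set_bc(net, inlets=("tl", "bl"), outlets=("tr", "br"))
        _add_sprout_4(net)
        if mid == "1D":
            _set_bc(net, outlets=("s4",))
            notes = f"model 1C plus one sprout (wall 4, outlet terminal) ({figure_note})"
        else:
            _set_bc(net, inlets=("s4",))
            notes = f"model 1D with terminal 4 flipped to a velocity inlet ({figure_note})"
        return ModelFixture(mid, net, notes)

    if mid in ("1E", "1G"):
        net = _model1_base()
        _set_bc(net, inlets=("tl", "bl"), outlets=("tr", "br"))
        _add_sprout_4(net)
        _set_bc(net, outlets=("s4",))
        _add_sprout_5(net)
        if mid == "1E":
            _set_bc(net, outlets=("s5",))
            notes = f"model 1C plus two sprouts (walls 4 and 5) ({figure_note})"
        else:
            _set_bc(net, inlets=("s5",))
            notes = f"model 1E with terminal 5 flipped to a velocity inlet ({figure_note})"
        return ModelFixture(mid, net, notes)

    # model-2 family
    net = _model2_base(angled_connector=(mid == "2B"))
    _set_bc(net, inlets=("tl", "bl"), outlets=("tr", "br", "s5"))
    if mid == "2C":
        _set_bc(net, inlets=("s5",))
        notes = f"complete network with terminal 5 flipped to a velocity inlet ({figure_note})"
    elif mid == "2B":
        notes = f"complete network with the vertical connector placed at an angle ({figure_note})"
    else:
        notes = f"complete network, all-outlet lower branch ({figure_note})"
    return ModelFixture(mid, net, notes)
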