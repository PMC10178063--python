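"""Wall-shear-stress binning, per-region intervals and the junction overlap.

Shear values are reported on a fixed contour grid (default bin width
0.42 Pa).  A raw ``[min, max]`` range is widened outward to bin edges; a
value sitting exactly on an edge belongs to the bin *below* it, so a wall
whose every segment carries 1.26 Pa reports the bin 0.84-1.26 Pa.  The
junction overlap region of a model is the intersection of the snapped
intervals of all its labelled junctions; intervals that merely touch at an
endpoint do not overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import NetworkFileError
from .solver import FlowSolution

__all__ = [
    "ShearInterval",
    "BinningScheme",
    "OverlapResult",
    "PhysiologicalRanges",
    "RegionSampleTable",
    "snap_to_bins",
    "wall_raw_range",
    "wall_interval",
    "junction_raw_range",
    "junction_interval",
    "intersect_intervals",
    "junction_overlap_region",
    "classify_physiological",
    "region_interval",
    "report_model_table",
    "write_report",
    "format_interval",
]

_EDGE_RTOL = 1e-9


@dataclass(frozen=True)
class ShearInterval:
    """A closed shear-stress interval in Pa; ``snapped`` marks bin-aligned
    endpoints."""

    low: float
    high: float
    snapped: bool = False

    def __post_init__(self):
        if self.low < 0 or self.high < self.low:
            raise ValueError(f"invalid interval [{self.low}, {self.high}]")

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def centre(self) -> float:
        return 0.5 * (self.low + self.high)


@dataclass(frozen=True)
class BinningScheme:
    """Contour grid for shear reporting.

    ``stagnation_floor`` (default one bin width) is the level below which an
    incident segment is treated as non-flowing when characterising a
    junction.
    """

    bin_width: float = 0.42
    max_edge: float = 4.20
    stagnation_floor: float = 0.42

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        ratio = self.max_edge / self.bin_width
        if abs(ratio - round(ratio)) > 1e-9 * max(1.0, abs(ratio)):
            raise ValueError("max_edge must be an integer multiple of bin_width")

    def bin_of(self, value: float) -> tuple[float, float]:
        """The contour bin containing ``value``.

        Values exactly on a bin edge (to relative tolerance 1e-9) belong to
        the bin below; zero belongs to the first bin.
        """
        if value < 0:
            raise ValueError("shear values are non-negative")
        w = self.bin_width
        ratio = value / w
        nearest = round(ratio)
        if abs(ratio - nearest) <= _EDGE_RTOL * max(1.0, abs(nearest)):
            k = max(int(nearest), 1)  # on an edge -> bin below (0 -> first bin)
        else:
            k = max(int(math.ceil(ratio)), 1)
        return ((k - 1) * w, k * w)


@dataclass(frozen=True)
class OverlapResult:
    """Outcome of intersecting per-junction intervals; ``interval`` is
    ``None`` when there is no positive-width overlap."""

    interval: Optional[ShearInterval]
    contributing: tuple[str, ...] = ()

    @property
    def is_empty(self) -> bool:
        return self.interval is None


@dataclass(frozen=True)
class PhysiologicalRanges:
    """Inclusive acceptance windows for arterial flow."""

    wss_low: float = 0.6
    wss_high: float = 4.0
    velocity_low: float = 0.049
    velocity_high: float = 0.19
    diameter_low: float = 0.0001
    diameter_high: float = 0.01

    def __post_init__(self):
        for lo, hi, name in ((self.wss_low, self.wss_high, "wss"),
                             (self.velocity_low, self.velocity_high, "velocity"),
                             (self.diameter_low, self.diameter_high, "diameter")):
            if not lo < hi:
                raise ValueError(f"{name} range must satisfy low < high")


def snap_to_bins(low: float, high: float, scheme: BinningScheme) -> ShearInterval:
    """Widen a raw [low, high] range outward to contour-bin edges."""
    if low > high:
        raise ValueError(f"low {low} exceeds high {high}")
    lo_bin = scheme.bin_of(low)
    hi_bin = scheme.bin_of(high)
    return ShearInterval(lo_bin[0], hi_bin[1], snapped=True)


def intersect_intervals(intervals: Sequence[ShearInterval]) -> OverlapResult:
    """Intersection of intervals; touching endpoints count as no overlap."""
    if not intervals:
        raise ValueError("need at least one interval")
    low = max(iv.low for iv in intervals)
    high = min(iv.high for iv in intervals)
    if high - low > 1e-12:
        snapped = all(iv.snapped for iv in intervals)
        return OverlapResult(ShearInterval(low, high, snapped=snapped))
    return OverlapResult(None)


# ---------------------------------------------------------------------------
# intervals from a flow solution
# ---------------------------------------------------------------------------


def wall_raw_range(solution: FlowSolution, wall_label: str) -> tuple[float, float]:
    shears = solution.segment_shears(wall_label)
    return (min(shears), max(shears))


def wall_interval(solution: FlowSolution, wall_label: str, scheme: BinningScheme) -> ShearInterval:
    """Snapped shear interval spanning all segments of one wall."""
    return snap_to_bins(*wall_raw_range(solution, wall_label), scheme)


def _junction_node(solution: FlowSolution, junction_name: str) -> str:
    labels = solution.network.junction_labels
    if junction_name not in labels:
        raise KeyError(f"unknown junction {junction_name!r}")
    return labels[junction_name]


def junction_raw_range(solution: FlowSolution, junction_name: str,
                       scheme: BinningScheme) -> tuple[float, float]:
    """Raw shear range over a junction's incident segments, with stagnant
    branches (below the stagnation floor) discarded whenever at least one
    incident segment flows."""
    shears = solution.incident_shears(_junction_node(solution, junction_name))
    if max(shears) > scheme.stagnation_floor:
        shears = [t for t in shears if t >= scheme.stagnation_floor]
    return (min(shears), max(shears))


def junction_interval(solution: FlowSolution, junction_name: str,
                      scheme: BinningScheme) -> ShearInterval:
    """Snapped hull over the binned shear of a junction's flowing branches."""
    return snap_to_bins(*junction_raw_range(solution, junction_name, scheme), scheme)


# ---------------------------------------------------------------------------
# external sample tables
# ---------------------------------------------------------------------------

_REGION_KINDS = ("wall", "junction")


class RegionSampleTable:
    """Labelled WSS samples (wall/junction regions) from an external solver
    or the synthetic generator.  Thin wrapper over a pandas frame with
    columns ``region_label``, ``region_kind``, ``wss_pa``."""

    COLUMNS = ("region_label", "region_kind", "wss_pa")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        bad_kind = ~frame["region_kind"].isin(_REGION_KINDS)
        if bad_kind.any():
            row = int(frame.index[bad_kind][0])
            raise ValueError(f"row {row}: region_kind must be one of {_REGION_KINDS}")
        if (frame["wss_pa"] < 0).any():
            row = int(frame.index[frame["wss_pa"] < 0][0])
            raise ValueError(f"row {row}: negative wss sample")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows) -> "RegionSampleTable":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def from_file(cls, path) -> "RegionSampleTable":
        """Read a delimited text file (tab or comma separated, header
        required).  Raises :class:`NetworkFileError` with row context."""
        try:
            frame = pd.read_csv(path, sep=None, engine="python")
        except Exception as exc:
            raise NetworkFileError(f"{path}: cannot parse sample table: {exc}") from exc
        if frame.empty:
            raise NetworkFileError(f"{path}: sample table has no data rows")
        try:
            frame["wss_pa"] = pd.to_numeric(frame["wss_pa"], errors="raise")
        except KeyError:
            raise NetworkFileError(f"{path}: missing column 'wss_pa'") from None
        except (TypeError, ValueError) as exc:
            raise NetworkFileError(f"{path}: non-numeric wss_pa value: {exc}") from exc
        try:
            return cls(frame)
        except ValueError as exc:
            raise NetworkFileError(f"{path}: {exc}") from exc

    def to_file(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def labels(self, kind: Optional[str] = None) -> list[str]:
        frame = self.frame
        if kind is not None:
            frame = frame[frame["region_kind"] == kind]
        return list(dict.fromkeys(frame["region_label"].astype(str)))

    def samples(self, label: str) -> list[float]:
        vals = self.frame.loc[self.frame["region_label"].astype(str) == str(label), "wss_pa"]
        if vals.empty:
            raise KeyError(f"no samples for region {label!r}")
        return [float(v) for v in vals]


def region_interval(table: RegionSampleTable, label: str, scheme: BinningScheme) -> ShearInterval:
    """Snapped interval spanning a region's samples."""
    vals = table.samples(label)
    return snap_to_bins(min(vals), max(vals), scheme)


# ---------------------------------------------------------------------------
# overlap statistic and classification
# ---------------------------------------------------------------------------


def junction_overlap_region(source: Union[FlowSolution, RegionSampleTable],
                            scheme: BinningScheme) -> OverlapResult:
    """Intersection of the snapped intervals of every junction region."""
    if isinstance(source, FlowSolution):
        names = sorted(source.network.junction_labels, key=_label_key)
        intervals = [junction_interval(source, name, scheme) for name in names]
    else:
        names = source.labels(kind="junction")
        intervals = [region_interval(source, name, scheme) for name in names]
    if not intervals:
        raise ValueError("no junction regions to intersect")
    result = intersect_intervals(intervals)
    return OverlapResult(result.interval, tuple(names))


def _label_key(label: str):
    try:
        return (0, float(label))
    except ValueError:
        return (1, label)


@dataclass(frozen=True)
class SegmentFlags:
    wss_ok: bool
    velocity_ok: bool
    diameter_ok: bool


def classify_physiological(solution: FlowSolution,
                           ranges: PhysiologicalRanges) -> dict[str, SegmentFlags]:
    """Inclusive threshold flags per segment (shear, |velocity|, diameter)."""
    out = {}
    for seg in solution.network.segments.values():
        tau = solution.wall_shear[seg.id]
        speed = abs(solution.mean_velocity[seg.id])
        diameter = 2 * seg.radius
        out[seg.id] = SegmentFlags(
            wss_ok=ranges.wss_low <= tau <= ranges.wss_high,
            velocity_ok=ranges.velocity_low <= speed <= ranges.velocity_high,
            diameter_ok=ranges.diameter_low <= diameter <= ranges.diameter_high,
        )
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

NO_OVERLAP = "No overlap"
VELOCITY_BIN_WIDTH = 0.055  # m/s


def format_interval(low: float, high: float) -> str:
    return f"{low:.3f}–{high:.3f}"


def _velocity_range(speeds: Sequence[float], bin_width: float) -> str:
    grid = BinningScheme(bin_width=bin_width, max_edge=bin_width,
                         stagnation_floor=bin_width)
    lo = grid.bin_of(min(speeds))[0]
    hi = grid.bin_of(max(speeds))[1]
    return format_interval(lo, hi)


def report_model_table(source: Union[FlowSolution, RegionSampleTable],
                       scheme: BinningScheme,
                       ranges: Optional[PhysiologicalRanges] = None,
                       velocity_bin: float = VELOCITY_BIN_WIDTH) -> pd.DataFrame:
    """One row per junction and wall with raw/snapped shear ranges, the
    model-wide junction overlap (repeated on junction rows) and, for solved
    networks, the binned velocity range."""
    overlap = junction_overlap_region(source, scheme)
    overlap_text = (NO_OVERLAP if overlap.is_empty
                    else format_interval(overlap.interval.low, overlap.interval.high))
    rows = []

    def add_row(location, raw, snapped, is_junction, speeds=None):
        rows.append({
            "location": location,
            "wss_raw_Pa": format_interval(*raw) if raw else "",
            "wss_range_Pa": format_interval(snapped.low, snapped.high),
            "junction_overlap_Pa": overlap_text if is_junction else "",
            "velocity_range_m_s": _velocity_range(speeds, velocity_bin) if speeds else "",
        })

    if isinstance(source, FlowSolution):
        net = source.network
        for name in sorted(net.junction_labels, key=_label_key):
            raw = junction_raw_range(source, name, scheme)
            node = net.junction_labels[name]
            speeds = [abs(source.mean_velocity[s.id]) for s in net.incident_segments(node)]
            add_row(f"Junction {name}", raw, junction_interval(source, name, scheme),
                    True, speeds)
        for wall in sorted(net.wall_labels(), key=_label_key):
            raw = wall_raw_range(source, wall)
            speeds = [abs(source.mean_velocity[s.id]) for s in net.wall_segments(wall)]
            add_row(f"Wall {wall}", raw, wall_interval(source, wall, scheme), False, speeds)
    else:
        for name in source.labels(kind="junction"):
            vals = source.samples(name)
            add_row(f"Junction {name}", (min(vals), max(vals)),
                    region_interval(source, name, scheme), True)
        for name in source.labels(kind="wall"):
            vals = source.samples(name)
            add_row(f"Wall {name}", (min(vals), max(vals)),
                    region_interval(source, name, scheme), False)
    return pd.DataFrame(rows)


def write_report(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)
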