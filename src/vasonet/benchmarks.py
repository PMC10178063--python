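"""Reported per-junction wall-shear-stress ranges for the benchmark models.

These are the published contour-level junction ranges (Pa) for the ten-model
benchmark family; they serve as regression fixtures for the overlap
statistic, independent of this package's reduced-order solver.  Endpoints
sit on the 0.42 Pa contour grid.
"""

from __future__ import annotations

from .shear import BinningScheme, OverlapResult, ShearInterval, intersect_intervals

__all__ = [
    "REPORTED_JUNCTION_INTERVALS",
    "REPORTED_OVERLAPS",
    "reported_junction_intervals",
    "reported_overlap",
]

#: (low, high) junction shear ranges per model, junction order 1..n
REPORTED_JUNCTION_INTERVALS: dict[str, tuple[tuple[float, float], ...]] = {
    "1C": ((0.420, 1.260), (0.840, 2.520)),
    "1D": ((0.420, 1.260), (0.840, 1.680), (0.840, 2.10)),
    "1E": ((0.420, 1.260), (0.840, 1.680), (0.840, 2.10), (0.420, 1.680)),
    "1F": ((0.420, 1.260), (0.840, 2.10), (1.260, 4.20)),
    "1G": ((0.420, 1.680), (0.840, 4.20), (0.840, 4.20), (1.260, 4.20)),
    "2A": ((0.420, 1.260), (0.840, 2.10), (0.420, 1.260),
           (0.840, 2.520), (0.420, 1.260), (0.840, 2.10)),
    "2B": ((0.420, 1.260), (0.420, 2.10), (0.420, 1.680),
           (0.840, 2.520), (0.840, 1.260), (0.840, 2.10)),
    "2C": ((0.420, 1.680), (0.840, 2.520), (0.840, 4.20),
           (1.680, 3.780), (2.10, 4.20), (0.840, 2.940)),
}

#: reported overlap region per model; None means "No overlap"
REPORTED_OVERLAPS: dict[str, tuple[float, float] | None] = {
    "1C": (0.840, 1.260),
    "1D": (0.840, 1.260),
    "1E": (0.840, 1.260),
    "1F": None,
    "1G": (1.260, 1.680),
    "2A": (0.840, 1.260),
    "2B": (0.840, 1.260),
    "2C": None,
}


def reported_junction_intervals(model_id: str,
                                scheme: BinningScheme | None = None) -> list[ShearInterval]:
    """The reported junction ranges of one model as snapped intervals."""
    if model_id not in REPORTED_JUNCTION_INTERVALS:
        raise KeyError(f"no reported junction intervals for model {model_id!r}")
    return [ShearInterval(lo, hi, snapped=True)
            for lo, hi in REPORTED_JUNCTION_INTERVALS[model_id]]


def reported_overlap(model_id: str) -> OverlapResult:
    """Recompute a model's junction overlap from its reported intervals."""
    return intersect_intervals(reported_junction_intervals(model_id))
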