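"""RECIST line geometry and the progressive-disease trigger.

A RECIST line is the lesion's longest axial diameter drawn on a single CT
slice. Progressive disease (PD) for a single lesion is an increase of >= 20%
in that diameter from its smallest size so far (the nadir, including the
pre-treatment baseline) that is also at least 5 mm in absolute terms. Only the
earliest PD scan enters the downstream analysis: it is the clinical decision
point.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RecistAnnotation", "MeasurementSeries", "recist_length", "find_pd_scan"]

PD_RELATIVE_INCREASE = 0.20  # >= 20% over the nadir
PD_ABSOLUTE_INCREASE_MM = 5.0  # and >= 5 mm absolute


@dataclass(frozen=True)
class RecistAnnotation:
    """Two endpoints (mm, world coordinates) on one axial slice."""

    p1: tuple[float, float, float]
    p2: tuple[float, float, float]
    slice_index: int
    scan_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "p1", tuple(float(v) for v in self.p1))
        object.__setattr__(self, "p2", tuple(float(v) for v in self.p2))
        if len(self.p1) != 3 or len(self.p2) != 3:
            raise ValueError("endpoints must be 3-vectors (mm)")
        if not np.isclose(self.p1[2], self.p2[2], atol=1e-9):
            raise ValueError(
                f"RECIST endpoints must lie on the same axial slice: z={self.p1[2]} vs z={self.p2[2]}"
            )

    @property
    def length_mm(self) -> float:
        return recist_length(self)

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.p1) + np.asarray(self.p2)) / 2.0


def recist_length(a: RecistAnnotation) -> float:
    """Euclidean in-plane length of the RECIST line in mm."""
    return float(np.linalg.norm(np.asarray(a.p1) - np.asarray(a.p2)))


@dataclass(frozen=True)
class MeasurementSeries:
    """Ordered RECIST lengths (mm) per scan; scan 0 is pre-treatment."""

    lengths_mm: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "lengths_mm", tuple(float(v) for v in self.lengths_mm))
        if len(self.lengths_mm) < 2:
            raise ValueError("a measurement series needs at least a baseline and one follow-up")
        if any(v <= 0 for v in self.lengths_mm):
            raise ValueError("all RECIST lengths must be strictly positive")

    def __len__(self) -> int:
        return len(self.lengths_mm)


def find_pd_scan(series) -> int | None:
    """Earliest follow-up scan meeting the single-lesion PD rule, or None.

    Scan t (t >= 1) triggers PD when length[t] >= 1.2 * nadir and
    length[t] - nadir >= 5 mm, where the nadir is the running minimum over
    scans 0..t (ties at exactly 20% / exactly 5 mm count as PD).
    """
    if not isinstance(series, MeasurementSeries):
        series = MeasurementSeries(tuple(series))
    lengths = series.lengths_mm
    nadir = lengths[0]
    for t in range(1, len(lengths)):
        nadir = min(nadir, lengths[t])
        if (
            lengths[t] >= (1.0 + PD_RELATIVE_INCREASE) * nadir
            and lengths[t] - nadir >= PD_ABSOLUTE_INCREASE_MM
        ):
            return t
    return None
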