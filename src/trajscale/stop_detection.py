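"""Anchor-distance/duration stop detection.

A *stop* (dwell episode) is a maximal run of fixes that all lie within
``delta_m`` metres of the run's first fix (the anchor) and whose span exceeds
``tau_min`` minutes. The scan is single-pass: points are assigned to the
current candidate while their distance to the anchor stays below δ; the first
point at distance ≥ δ breaks the candidate, the dwell time between the anchor
and the last assigned point decides emission (dwell > τ), and the scan
restarts at the breaking point whether or not the candidate was emitted. The
trailing candidate at the end of the trajectory is emitted if it passes the
dwell test.

Published operating point for herring-gull GPS at ~2-minute sampling:
δ = 150 m, τ = 18 min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import Trajectory, haversine_m

__all__ = [
    "StopDetectionParams",
    "StopPoint",
    "detect_stops",
    "sensitivity_sweep",
    "match_planted_stops",
    "stops_to_frame",
]


@dataclass(frozen=True)
class StopDetectionParams:
    """Spatial (δ, metres) and temporal (τ, minutes) stop thresholds."""

    delta_m: float = 150.0
    tau_min: float = 18.0

    def __post_init__(self) -> None:
        if self.delta_m <= 0 or self.tau_min <= 0:
            raise ValueError("delta_m and tau_min must be positive")


@dataclass(frozen=True)
class StopPoint:
    """A dwell episode: centroid, time interval, and member-fix count."""

    individual_id: str
    centroid_lon: float
    centroid_lat: float
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    n_fixes: int


def detect_stops(traj: Trajectory, params: StopDetectionParams) -> list[StopPoint]:
    """Segment a time-sorted trajectory into stop-points.

    Returns stops ordered by ``t_start`` and non-overlapping in time. A
    trajectory with fewer than 2 fixes yields no stops (a single fix has zero
    dwell).
    """
    n = len(traj)
    if n < 2:
        return []
    lons, lats = traj.lons, traj.lats
    t_ns = traj.times.asi8  # int64 nanoseconds
    tau_ns = int(params.tau_min * 60 * 1e9)
    delta = params.delta_m

    stops: list[StopPoint] = []
    i = 0
    while i < n:
        anchor = i
        # distances from every later point to the anchor, vectorised;
        # the candidate ends at the first point at distance >= delta.
        d = haversine_m(lons[anchor], lats[anchor], lons[anchor + 1 :], lats[anchor + 1 :])
        breaks = np.nonzero(d >= delta)[0]
        j = anchor + 1 + breaks[0] if len(breaks) else n
        # candidate members are anchor .. j-1
        dwell_ns = t_ns[j - 1] - t_ns[anchor]
        if dwell_ns > tau_ns:
            members = slice(anchor, j)
            stops.append(
                StopPoint(
                    individual_id=traj.individual_id,
                    centroid_lon=float(np.mean(lons[members])),
                    centroid_lat=float(np.mean(lats[members])),
                    t_start=traj.times[anchor],
                    t_end=traj.times[j - 1],
                    n_fixes=j - anchor,
                )
            )
        i = j  # restart at the breaking point (or terminate at the end)
    return stops


def sensitivity_sweep(
    traj: Trajectory, deltas: list[float], taus: list[float]
) -> np.ndarray:
    """Stop counts over a δ × τ parameter grid.

    Returns an integer matrix of shape ``(len(deltas), len(taus))`` whose cell
    (i, j) is the number of stops detected at ``(deltas[i], taus[j])``. Used
    to choose the operating point the way the published analysis did.
    """
    if not deltas or not taus:
        raise ValueError("deltas and taus must be non-empty")
    grid = np.zeros((len(deltas), len(taus)), dtype=int)
    for i, d in enumerate(deltas):
        for j, t in enumerate(taus):
            grid[i, j] = len(detect_stops(traj, StopDetectionParams(d, t)))
    return grid


def match_planted_stops(
    detected: list[StopPoint],
    planted: list,
    delta_m: float,
) -> tuple[float, float]:
    """Precision and recall of detected stops against planted ground truth.

    A detected stop matches a planted stay if their centroids are within
    ``delta_m`` metres and their time intervals overlap. ``planted`` items
    need ``centroid_lon``, ``centroid_lat``, ``t_start``, ``t_end``
    attributes (e.g. planted :class:`StopPoint` records from the synthetic
    GPS generator).

    Returns ``(precision, recall)``; both are 1.0 on empty detected/planted
    sets respectively (nothing to get wrong).
    """

    def overlaps(a, b) -> bool:
        return a.t_start <= b.t_end and b.t_start <= a.t_end

    def near(a, b) -> bool:
        return (
            float(
                haversine_m(a.centroid_lon, a.centroid_lat, b.centroid_lon, b.centroid_lat)
            )
            <= delta_m
        )

    matched_detected = sum(
        1 for d in detected if any(near(d, p) and overlaps(d, p) for p in planted)
    )
    matched_planted = sum(
        1 for p in planted if any(near(d, p) and overlaps(d, p) for d in detected)
    )
    precision = matched_detected / len(detected) if detected else 1.0
    recall = matched_planted / len(planted) if planted else 1.0
    return precision, recall


def stops_to_frame(stops: list[StopPoint]) -> pd.DataFrame:
    """Stops as a DataFrame with the canonical output columns."""
    return pd.DataFrame(
        [
            {
                "id": s.individual_id,
                "centroid_lon": s.centroid_lon,
                "centroid_lat": s.centroid_lat,
                "t_start": s.t_start,
                "t_end": s.t_end,
                "n_fixes": s.n_fixes,
            }
            for s in stops
        ],
        columns=["id", "centroid_lon", "centroid_lat", "t_start", "t_end", "n_fixes"],
    )
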