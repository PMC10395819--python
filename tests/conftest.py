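"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trajscale.stop_detection import StopPoint
from trajscale.trajectory_io import Trajectory, geodesic_distance_m

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

T0 = pd.Timestamp("2017-03-01 00:00:00", tz="UTC")


# ---------------------------------------------------------------------------
# random-instance builders
# ---------------------------------------------------------------------------


def make_trajectory(times_min, lons, lats, individual_id="bird-1") -> Trajectory:
    """Trajectory from minute offsets and coordinate lists."""
    return Trajectory(
        individual_id=individual_id,
        times=pd.DatetimeIndex([T0 + pd.Timedelta(minutes=float(m)) for m in times_min]),
        lons=np.asarray(lons, dtype=float),
        lats=np.asarray(lats, dtype=float),
    )


def random_trajectory(rng: np.random.Generator, n_fixes: int = 50) -> Trajectory:
    """A random dwell/transit mixture exercising both detector branches.

    Step lengths alternate between sub-δ jitter (dwelling) and multi-hundred
    metre jumps (moving), with ~2-minute jittered sampling.
    """
    lon, lat = 2.9, 51.2
    lons, lats, tmins = [], [], []
    t = 0.0
    dwelling = True
    for _ in range(n_fixes):
        lons.append(lon)
        lats.append(lat)
        tmins.append(t)
        t += rng.uniform(1.0, 3.0)
        if rng.random() < 0.15:
            dwelling = not dwelling
        step_m = rng.uniform(0.0, 60.0) if dwelling else rng.uniform(100.0, 600.0)
        theta = rng.uniform(0, 2 * np.pi)
        lat += np.degrees(step_m * np.sin(theta) / 6_371_008.8)
        lon += np.degrees(step_m * np.cos(theta) / (6_371_008.8 * np.cos(np.radians(lat))))
    return make_trajectory(tmins, lons, lats)


def random_stops(rng: np.random.Generator, n: int = 30) -> list[StopPoint]:
    """Random stop-points scattered over a few km, sequential time intervals."""
    stops = []
    t = T0
    for k in range(n):
        lon = 2.9 + rng.uniform(0, 0.03)
        lat = 51.2 + rng.uniform(0, 0.02)
        dur = pd.Timedelta(minutes=float(rng.uniform(20, 60)))
        stops.append(StopPoint("bird-1", lon, lat, t, t + dur, int(rng.integers(2, 20))))
        t = t + dur + pd.Timedelta(minutes=5)
    return stops


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_detect_stops(traj: Trajectory, delta_m: float, tau_min: float):
    """Brute-force transcription of the anchor-distance/duration stop scan.

    Walks point by point keeping an explicit member list: assign while the
    distance to the candidate's first point is below delta; at the first
    point at or beyond delta, emit the candidate iff the time from its first
    to its last member exceeds tau, then restart at the breaking point. The
    trailing candidate is emitted under the same dwell test.

    Returns a list of (centroid_lon, centroid_lat, t_start, t_end, n_fixes).
    """
    n = len(traj)
    if n < 2:
        return []
    tau_s = tau_min * 60.0
    out = []

    def emit(members):
        dwell = (traj.times[members[-1]] - traj.times[members[0]]).total_seconds()
        if dwell > tau_s:
            out.append(
                (
                    float(np.mean([traj.lons[k] for k in members])),
                    float(np.mean([traj.lats[k] for k in members])),
                    traj.times[members[0]],
                    traj.times[members[-1]],
                    len(members),
                )
            )

    members = [0]
    j = 1
    while j < n:
        anchor = members[0]
        d = geodesic_distance_m(
            (traj.lons[j], traj.lats[j]), (traj.lons[anchor], traj.lats[anchor])
        )
        if d < delta_m:
            members.append(j)
        else:
            emit(members)
            members = [j]
        j += 1
    emit(members)
    return out


def oracle_connected_components(stops: list[StopPoint], eps_m: float) -> list[set[int]]:
    """Connected components of the ε-ball graph over stop centroids (BFS)."""
    n = len(stops)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = geodesic_distance_m(
                (stops[i].centroid_lon, stops[i].centroid_lat),
                (stops[j].centroid_lon, stops[j].centroid_lat),
            )
            if d <= eps_m:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        comp, queue = set(), [s]
        seen[s] = True
        while queue:
            u = queue.pop()
            comp.add(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    queue.append(v)
        comps.append(comp)
    return comps


@pytest.fixture
def rng():
    return np.random.default_rng(20170101)
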