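"""Reading, validating and partitioning raw GPS fix tables.

Raw input is a CSV of timestamped GPS fixes in the Movebank export dialect
(one row per fix: individual identifier, UTC timestamp, longitude, latitude).
This module normalises those rows into per-individual :class:`Trajectory`
objects with strictly increasing timestamps, and provides the geodesic
distance primitive that the stop-detection (δ) and clustering (ϵ) thresholds
are measured in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Fix",
    "Trajectory",
    "ReadReport",
    "DEFAULT_COLUMN_MAP",
    "read_fixes",
    "write_fixes",
    "geodesic_distance_m",
    "haversine_m",
    "split_by_month",
]

logger = logging.getLogger(__name__)

#: Mean Earth radius (IUGG), metres.
EARTH_RADIUS_M = 6_371_008.8

#: Movebank CSV export column names -> canonical field names.
DEFAULT_COLUMN_MAP = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
}

#: Canonical column names used for normalised output.
CANONICAL_COLUMNS = ["id", "timestamp", "lon", "lat"]


@dataclass(frozen=True)
class Fix:
    """One timestamped GPS observation of one individual."""

    individual_id: str
    timestamp: pd.Timestamp
    lon: float
    lat: float


@dataclass
class Trajectory:
    """The time-ordered raw trajectory of one individual.

    Coordinates are stored as flat numpy arrays and timestamps as a tz-aware
    UTC ``DatetimeIndex``; the invariant is strictly increasing timestamps.
    """

    individual_id: str
    times: pd.DatetimeIndex
    lons: np.ndarray
    lats: np.ndarray

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        if not (len(self.times) == len(self.lons) == len(self.lats)):
            raise ValueError("times, lons and lats must have equal length")
        if self.times.tz is None:
            raise ValueError("trajectory timestamps must be timezone-aware (UTC)")
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValueError("trajectory timestamps must be increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def fixes(self) -> list[Fix]:
        return [
            Fix(self.individual_id, t, lo, la)
            for t, lo, la in zip(self.times, self.lons, self.lats)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.individual_id,
                "timestamp": self.times,
                "lon": self.lons,
                "lat": self.lats,
            }
        )


@dataclass
class ReadReport:
    """Row-level accounting for one :func:`read_fixes` call."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped_invalid: int = 0
    n_dropped_duplicate_time: int = 0
    warnings: list[str] = field(default_factory=list)


def _validate_coords(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    return (
        np.isfinite(lon)
        & np.isfinite(lat)
        & (lat >= -90.0)
        & (lat <= 90.0)
        & (lon >= -180.0)
        & (lon <= 180.0)
    )


def read_fixes(
    path,
    column_map: dict | None = None,
    timestamp_format: str | None = None,
    report: ReadReport | None = None,
) -> list[Trajectory]:
    """Read a Movebank-dialect CSV of GPS fixes into per-individual trajectories.

    Parameters
    ----------
    path:
        CSV file with a header row.
    column_map:
        Mapping from canonical field names (``individual_id``, ``timestamp``,
        ``lon``, ``lat``) to the CSV's column names. Defaults to the Movebank
        export dialect.
    timestamp_format:
        Optional strftime pattern; by default ISO-8601 is parsed.
    report:
        Optional :class:`ReadReport` to fill with drop counts.

    Returns
    -------
    list of Trajectory, sorted by individual id. Per individual, fixes are
    sorted by timestamp; exact-duplicate timestamps collapse to the first
    occurrence; rows with unparseable coordinates or timestamps are dropped
    and counted.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    rep = report if report is not None else ReadReport()

    raw = pd.read_csv(path, dtype=str)
    rep.n_rows = len(raw)
    missing = [c for c in cmap.values() if c not in raw.columns]
    if missing:
        raise KeyError(f"mapped columns missing from CSV: {missing}")
    if raw.empty:
        msg = f"{path}: no data rows"
        rep.warnings.append(msg)
        logger.warning(msg)
        return []

    df = pd.DataFrame(
        {
            "id": raw[cmap["individual_id"]].astype(str),
            "timestamp": pd.to_datetime(
                raw[cmap["timestamp"]],
                format=timestamp_format,
                errors="coerce",
                utc=True,
            ),
            "lon": pd.to_numeric(raw[cmap["lon"]], errors="coerce"),
            "lat": pd.to_numeric(raw[cmap["lat"]], errors="coerce"),
        }
    )
    valid = df["timestamp"].notna() & _validate_coords(
        df["lon"].to_numpy(), df["lat"].to_numpy()
    )
    rep.n_dropped_invalid = int((~valid).sum())
    if rep.n_dropped_invalid:
        logger.info("dropped %d invalid rows from %s", rep.n_dropped_invalid, path)
    df = df[valid]

    df = df.sort_values(["id", "timestamp"], kind="mergesort")
    dup = df.duplicated(subset=["id", "timestamp"], keep="first")
    rep.n_dropped_duplicate_time = int(dup.sum())
    df = df[~dup]
    rep.n_kept = len(df)

    trajectories = []
    for ind, grp in df.groupby("id", sort=True):
        trajectories.append(
            Trajectory(
                individual_id=str(ind),
                times=pd.DatetimeIndex(grp["timestamp"]),
                lons=grp["lon"].to_numpy(),
                lats=grp["lat"].to_numpy(),
            )
        )
    return trajectories


def write_fixes(trajectories: list[Trajectory], path) -> None:
    """Write trajectories to the canonical normalised CSV (``id,timestamp,lon,lat``)."""
    frames = [t.to_frame() for t in trajectories]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CANONICAL_COLUMNS)
    )
    out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S%z")


def haversine_m(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Vectorised haversine distance in metres on the mean-Earth-radius sphere."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geodesic_distance_m(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Geodesic (great-circle) distance between two (lon, lat) points, metres.

    Haversine on a sphere of radius 6371.0088 km. Non-negative and symmetric.
    """
    lon1, lat1 = a
    lon2, lat2 = b
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if not (np.isfinite(lon) and np.isfinite(lat)):
            raise ValueError(f"non-finite coordinate: {(lon, lat)}")
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            raise ValueError(f"coordinate out of range: {(lon, lat)}")
    return float(haversine_m(lon1, lat1, lon2, lat2))


def split_by_month(traj: Trajectory) -> dict[tuple[int, int], Trajectory]:
    """Partition a trajectory into UTC calendar months.

    Returns a mapping ``(year, month) -> Trajectory``; every fix lands in
    exactly one month and the union of the outputs equals the input.
    """
    if len(traj) == 0:
        return {}
    keys = list(zip(traj.times.year, traj.times.month))
    out: dict[tuple[int, int], Trajectory] = {}
    arr = np.array(keys)
    for ym in sorted(set(keys)):
        mask = (arr[:, 0] == ym[0]) & (arr[:, 1] == ym[1])
        out[ym] = Trajectory(
            individual_id=traj.individual_id,
            times=traj.times[mask],
            lons=traj.lons[mask],
            lats=traj.lats[mask],
        )
    return out
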