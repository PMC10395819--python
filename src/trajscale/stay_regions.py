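"""Spatial aggregation of stop-points into stay-regions.

Stop-points are clustered with DBSCAN under the geodesic (haversine) metric.
With a minimum neighbourhood size of 2 (self-inclusive), DBSCAN degenerates
to the connected components of the graph linking stops within ``eps_m``
metres; a stay-region is a component with at least ``min_stops`` members.
Smaller components are noise: dropped by default, or kept as singleton
regions when ``keep_singletons`` is set. Each surviving stop becomes one
:class:`Visit` carrying its stop's time interval and its region's label.

Published operating points: ϵ = 400 m for gull data, ϵ = 200 m for the
human comparison data; a region needs at least two stop-points.

An alternative complete-linkage mode (every pair of member stops within ϵ)
is available via ``linkage="complete"`` for sensitivity checks; DBSCAN
chaining is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import DBSCAN

from .stop_detection import StopPoint
from .trajectory_io import EARTH_RADIUS_M, haversine_m

__all__ = [
    "ClusteringParams",
    "StayRegion",
    "Visit",
    "cluster_stops",
    "region_count_by_month",
    "mean_region_count_by_month",
]


@dataclass(frozen=True)
class ClusteringParams:
    """Stay-region clustering parameters (ϵ in metres)."""

    eps_m: float = 400.0
    min_stops: int = 2
    keep_singletons: bool = False
    linkage: str = "dbscan"  # "dbscan" (chained ε-neighbourhoods) | "complete"

    def __post_init__(self) -> None:
        if self.eps_m <= 0:
            raise ValueError("eps_m must be positive")
        if self.min_stops < 2:
            raise ValueError("min_stops must be at least 2")
        if self.linkage not in ("dbscan", "complete"):
            raise ValueError(f"unknown linkage: {self.linkage!r}")


@dataclass(frozen=True)
class StayRegion:
    """A cluster of stop-points treated as one place."""

    region_id: int
    centroid_lon: float
    centroid_lat: float
    n_stops: int


@dataclass(frozen=True)
class Visit:
    """One labelled dwell episode: a stop assigned to a stay-region."""

    individual_id: str
    region_id: int
    t_start: pd.Timestamp
    t_end: pd.Timestamp


@dataclass
class ClusterReport:
    """Accounting for one clustering call."""

    n_stops: int = 0
    n_noise: int = 0
    n_regions: int = 0
    extra: dict = field(default_factory=dict)


def _raw_labels(lons: np.ndarray, lats: np.ndarray, params: ClusteringParams) -> np.ndarray:
    """Component labels before the min-size / singleton policy (−1 never used)."""
    n = len(lons)
    if n == 1:
        return np.zeros(1, dtype=int)
    if params.linkage == "dbscan":
        coords = np.radians(np.column_stack([lats, lons]))
        db = DBSCAN(
            eps=params.eps_m / EARTH_RADIUS_M, min_samples=2, metric="haversine"
        ).fit(coords)
        labels = db.labels_.copy()
        # DBSCAN noise points are ε-graph singletons; give each its own label
        # so the size policy below is the single place noise is decided.
        nxt = labels.max() + 1
        for k in np.nonzero(labels == -1)[0]:
            labels[k] = nxt
            nxt += 1
        return labels
    # complete linkage: all pairwise member distances < eps
    dm = haversine_m(
        lons[:, None], lats[:, None], lons[None, :], lats[None, :]
    )
    z = scipy_linkage(squareform(dm, checks=False), method="complete")
    return fcluster(z, t=params.eps_m, criterion="distance") - 1


def cluster_stops(
    stops: list[StopPoint],
    params: ClusteringParams,
    report: ClusterReport | None = None,
) -> tuple[list[StayRegion], list[Visit]]:
    """Cluster stop-points into stay-regions and emit labelled visits.

    Region ids are dense from 0, assigned in order of each region's first
    visit (earliest member ``t_start``), which makes labels deterministic.
    Visits are returned in chronological order, one per surviving stop, with
    time intervals untouched by clustering.
    """
    rep = report if report is not None else ClusterReport()
    rep.n_stops = len(stops)
    if not stops:
        return [], []
    order = np.argsort([s.t_start for s in stops], kind="stable")
    stops = [stops[k] for k in order]
    lons = np.array([s.centroid_lon for s in stops])
    lats = np.array([s.centroid_lat for s in stops])

    labels = _raw_labels(lons, lats, params)

    sizes = pd.Series(labels).value_counts()
    surviving = set(sizes[sizes >= params.min_stops].index)
    noise = [k for k, lab in enumerate(labels) if lab not in surviving]
    rep.n_noise = len(noise)

    # relabel: surviving components (plus singletons if kept) densely from 0,
    # in order of first appearance in time.
    final = np.full(len(stops), -1, dtype=int)
    relabel: dict[int, int] = {}
    nxt = 0
    for k, lab in enumerate(labels):
        if lab in surviving or params.keep_singletons:
            if lab not in relabel:
                relabel[lab] = nxt
                nxt += 1
            final[k] = relabel[lab]

    regions: list[StayRegion] = []
    for rid in range(nxt):
        members = np.nonzero(final == rid)[0]
        regions.append(
            StayRegion(
                region_id=rid,
                centroid_lon=float(np.mean(lons[members])),
                centroid_lat=float(np.mean(lats[members])),
                n_stops=len(members),
            )
        )
    visits = [
        Visit(
            individual_id=stops[k].individual_id,
            region_id=int(final[k]),
            t_start=stops[k].t_start,
            t_end=stops[k].t_end,
        )
        for k in range(len(stops))
        if final[k] >= 0
    ]
    rep.n_regions = len(regions)
    return regions, visits


def region_count_by_month(visits: list[Visit]) -> pd.DataFrame:
    """Distinct stay-regions visited per individual per UTC calendar month.

    A visit is assigned to the month of its start time. Returns a DataFrame
    with columns ``id, year, month, n_regions``.
    """
    if not visits:
        return pd.DataFrame(columns=["id", "year", "month", "n_regions"])
    df = pd.DataFrame(
        {
            "id": [v.individual_id for v in visits],
            "year": [v.t_start.year for v in visits],
            "month": [v.t_start.month for v in visits],
            "region_id": [v.region_id for v in visits],
        }
    )
    out = (
        df.groupby(["id", "year", "month"])["region_id"]
        .nunique()
        .rename("n_regions")
        .reset_index()
    )
    return out


def mean_region_count_by_month(visits: list[Visit]) -> pd.Series:
    """Mean (across individuals) distinct-region count per (year, month)."""
    per = region_count_by_month(visits)
    if per.empty:
        return pd.Series(dtype=float)
    return per.groupby(["year", "month"])["n_regions"].mean()
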