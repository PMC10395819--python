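"""Mobility statistics and scaling-exponent fits.

Three standard metrics of individual mobility:

* **Radius of gyration** ``r_g = sqrt((1/N) Σ w_i d(r_i, r_0)^2 / Σ w_i)`` —
  the root-mean-square geodesic distance of a set of (possibly weighted)
  locations from their centre of mass; the typical travel scale.
* **Visitation frequency** ``f_r`` — the fraction of all visits going to the
  r-th most-visited stay-region; its rank decay ``f_r ~ r^{-ζ}`` is the Zipf
  law of mobility.
* **Distinct locations over time** ``S(t)`` — the cumulative number of
  distinct stay-regions seen by time t; sublinear growth ``S(t) ~ t^{μ}``
  (μ < 1) signals decreasing exploration.

Exponents are obtained by ordinary least squares of log10(y) on log10(x)
over the full curve.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stay_regions import StayRegion
from .temporal_aggregation import GAP, SymbolSequence

__all__ = [
    "RankCurve",
    "GrowthCurve",
    "ScalingFit",
    "AveragedCurve",
    "radius_of_gyration",
    "sequence_radius_of_gyration",
    "visitation_frequency",
    "distinct_over_time",
    "fit_exponent",
    "population_curve",
]


@dataclass
class RankCurve:
    """Visitation frequencies by rank: f_1 ≥ f_2 ≥ … , Σ f_r = 1."""

    ranks: np.ndarray
    frequencies: np.ndarray
    region_ids: np.ndarray  # regions in rank order (ties broken by id)

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(self.frequencies) > 1e-12):
            raise ValueError("rank-curve frequencies must be non-increasing")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("rank-curve frequencies must sum to 1")


@dataclass
class GrowthCurve:
    """Distinct locations S(t) along a sequence's time axis t = 1..T."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.counts) < 0):
            raise ValueError("growth curve must be non-decreasing")


@dataclass(frozen=True)
class ScalingFit:
    """A fitted power-law exponent with diagnostics.

    ``exponent`` is the magnitude of the log-log slope (reported positive for
    both the Zipf decay ζ and the exploration growth μ); ``slope`` keeps the
    sign. ``intercept`` is in log10 space.
    """

    exponent: float
    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class AveragedCurve:
    """Pointwise mean of several curves; n_curves[k] individuals cover point k."""

    x: np.ndarray
    mean_y: np.ndarray
    n_curves: np.ndarray


def radius_of_gyration(
    points: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Radius of gyration (metres) of (lon, lat) points about their centroid.

    The centre of mass is the (weighted) arithmetic mean of the coordinates —
    valid at the sub-degree extents of dwell-location sets — and deviations
    are geodesic distances, combined as a weighted root mean square.
    """
    from .trajectory_io import haversine_m

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("radius_of_gyration needs at least one point")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(pts) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    lon0 = float(np.average(pts[:, 0], weights=w))
    lat0 = float(np.average(pts[:, 1], weights=w))
    d = haversine_m(pts[:, 0], pts[:, 1], lon0, lat0)
    return float(np.sqrt(np.average(d**2, weights=w)))


def sequence_radius_of_gyration(
    seq: SymbolSequence, regions: list[StayRegion]
) -> float:
    """Radius of gyration of a symbolic sequence.

    Each visited stay-region contributes its centroid, weighted by the number
    of occurrences of its symbol in the sequence (GAP bins excluded).
    """
    counts = Counter(seq.non_gap_symbols)
    if not counts:
        raise ValueError("sequence has no non-GAP symbols")
    lookup = {r.region_id: (r.centroid_lon, r.centroid_lat) for r in regions}
    pts = np.array([lookup[rid] for rid in counts])
    w = np.array([counts[rid] for rid in counts], dtype=float)
    return radius_of_gyration(pts, w)


def visitation_frequency(seq: SymbolSequence) -> RankCurve:
    """Rank-ordered visit frequencies of a sequence.

    NTB: every non-GAP bin is one visit (self-transitions inflate counts);
    NP: every event is one visit. Ties in frequency are ordered by region id.
    """
    counts = Counter(seq.non_gap_symbols)
    if not counts:
        raise ValueError("sequence has no non-GAP symbols")
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    freqs = np.array([c for _, c in items], dtype=float) / total
    return RankCurve(
        ranks=np.arange(1, len(items) + 1),
        frequencies=freqs,
        region_ids=np.array([r for r, _ in items]),
    )


def distinct_over_time(seq: SymbolSequence) -> GrowthCurve:
    """Cumulative distinct-region count along the sequence.

    The time axis is the bin index for NTB (GAP bins advance t but leave S
    flat) and the event index for NP; t runs 1..T.
    """
    seen: set[int] = set()
    counts = np.empty(len(seq.symbols), dtype=int)
    for k, s in enumerate(seq.symbols):
        if s != GAP:
            seen.add(s)
        counts[k] = len(seen)
    return GrowthCurve(times=np.arange(1, len(counts) + 1), counts=counts)


def fit_exponent(x, y) -> ScalingFit:
    """OLS power-law fit: regress log10(y) on log10(x).

    Only strictly positive (x, y) pairs enter the fit; at least three are
    required. ``exponent`` is |slope|: use it as ζ for decay curves and μ for
    growth curves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("fit_exponent needs at least 3 positive points")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(ly) == 0.0:  # constant y: exact zero-slope fit
        return ScalingFit(0.0, 0.0, float(ly[0]), 1.0, len(x))
    res = stats.linregress(lx, ly)
    return ScalingFit(
        exponent=abs(float(res.slope)),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=len(x),
    )


def population_curve(curves: list) -> AveragedCurve:
    """Pointwise mean of rank or growth curves across individuals.

    Curves may have unequal lengths; each point averages only the individuals
    whose curve extends that far. The collective scaling exponents ζ and μ
    are fitted on this averaged curve.
    """
    if not curves:
        raise ValueError("population_curve needs at least one curve")
    ys = []
    for c in curves:
        if isinstance(c, RankCurve):
            ys.append(np.asarray(c.frequencies, dtype=float))
        elif isinstance(c, GrowthCurve):
            ys.append(np.asarray(c.counts, dtype=float))
        else:
            ys.append(np.asarray(c, dtype=float))
    T = max(len(y) for y in ys)
    stacked = np.full((len(ys), T), np.nan)
    for i, y in enumerate(ys):
        stacked[i, : len(y)] = y
    n = np.sum(~np.isnan(stacked), axis=0)
    mean = np.nanmean(stacked, axis=0)
    return AveragedCurve(x=np.arange(1, T + 1), mean_y=mean, n_curves=n)
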