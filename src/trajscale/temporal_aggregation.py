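"""Temporal aggregation of labelled visits into symbolic sequences.

Two schemes are supported:

* **Next Time-Bin (NTB)** — one symbol per fixed-width time bin (default one
  hour, bins anchored at the top of the UTC hour). The symbol is the
  stay-region with the longest dwell overlap inside the bin; a duration tie
  goes to the region with the higher visit count over the whole sequence,
  and a residual tie to the smallest region id. Bins with no stay-region
  time are kept as ``GAP`` so the calendar time axis stays intact.
  Consecutive identical symbols (self-transitions) are preserved.

* **Next Place (NP)** — the sequence of regions in visit order with
  consecutive duplicates collapsed, so the sequence contains only
  transitions between stay-regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd

from .stay_regions import Visit

__all__ = ["GAP", "SymbolSequence", "aggregate_ntb", "aggregate_np"]

#: Sentinel symbol for an NTB bin with no stay-region time. Region ids are
#: dense from 0, so -1 is never a region.
GAP = -1


@dataclass
class SymbolSequence:
    """A time-ordered symbolic trajectory over stay-region ids."""

    individual_id: str
    scheme: str  # "ntb" | "np"
    symbols: list[int]
    bin_width: pd.Timedelta | None = None
    t0: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("ntb", "np"):
            raise ValueError(f"unknown scheme: {self.scheme!r}")
        if self.scheme == "np":
            if any(s == GAP for s in self.symbols):
                raise ValueError("NP sequences cannot contain GAP symbols")
            for a, b in zip(self.symbols, self.symbols[1:]):
                if a == b:
                    raise ValueError("NP sequences cannot contain self-transitions")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def non_gap_symbols(self) -> list[int]:
        return [s for s in self.symbols if s != GAP]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, s in enumerate(self.symbols):
            ts = (
                (self.t0 + k * self.bin_width).isoformat()
                if self.scheme == "ntb" and self.t0 is not None
                else k
            )
            rows.append(
                {
                    "id": self.individual_id,
                    "scheme": self.scheme,
                    "position": k,
                    "timestamp_or_index": ts,
                    "symbol": s,
                }
            )
        return pd.DataFrame(
            rows, columns=["id", "scheme", "position", "timestamp_or_index", "symbol"]
        )


def aggregate_ntb(
    visits: list[Visit], bin_width: pd.Timedelta = pd.Timedelta(hours=1)
) -> SymbolSequence:
    """Build the Next Time-Bin sequence of one individual's visits.

    Bins run from the first visit's start (floored to the top of the UTC
    hour) to the last visit's end; bin count = ceil(span / bin_width).
    """
    if not visits:
        return SymbolSequence("", "ntb", [], bin_width=bin_width)
    individual = visits[0].individual_id
    visits = sorted(visits, key=lambda v: (v.t_start, v.t_end))
    t0 = visits[0].t_start.floor("h")
    t_last = max(v.t_end for v in visits)
    span_ns = (t_last - t0).value
    width_ns = bin_width.value
    n_bins = max(1, int(np.ceil(span_ns / width_ns)))

    # whole-sequence visit counts, for the duration tie-break
    visit_counts = Counter(v.region_id for v in visits)

    starts = np.array([v.t_start.value for v in visits])
    ends = np.array([v.t_end.value for v in visits])
    regions = np.array([v.region_id for v in visits])
    t0_ns = t0.value

    symbols: list[int] = []
    for k in range(n_bins):
        lo = t0_ns + k * width_ns
        hi = lo + width_ns
        overlap = np.minimum(ends, hi) - np.maximum(starts, lo)
        overlap = np.where(overlap > 0, overlap, 0)
        if overlap.sum() == 0:
            symbols.append(GAP)
            continue
        per_region: dict[int, int] = {}
        for r, o in zip(regions, overlap):
            if o > 0:
                per_region[int(r)] = per_region.get(int(r), 0) + int(o)
        # longest dwell; tie -> most-visited region; tie -> smallest id
        best = min(
            per_region.items(),
            key=lambda kv: (-kv[1], -visit_counts[kv[0]], kv[0]),
        )[0]
        symbols.append(best)
    return SymbolSequence(individual, "ntb", symbols, bin_width=bin_width, t0=t0)


def aggregate_np(visits: list[Visit]) -> SymbolSequence:
    """Build the Next Place sequence: visit order with repeats collapsed."""
    if not visits:
        return SymbolSequence("", "np", [])
    individual = visits[0].individual_id
    visits = sorted(visits, key=lambda v: (v.t_start, v.t_end))
    symbols: list[int] = []
    for v in visits:
        if not symbols or symbols[-1] != v.region_id:
            symbols.append(v.region_id)
    return SymbolSequence(individual, "np", symbols)
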