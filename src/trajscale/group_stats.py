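"""Group significance comparisons of per-individual-month metric values.

Two non-parametric tests suitable for small samples are applied to the same
pair of samples: the two-sample Kolmogorov-Smirnov test (are the two
distributions identical?) and the Kruskal-Wallis test (do the groups share a
central tendency?). Results are flagged at α = 0.05 (``✓``) and α = 0.1
(``*``), mirroring the published significance grid over
{breeding vs non-breeding, male vs female, study species vs comparison
population} × {f_r, r_g, S(t)} × {NP, NTB}.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "GroupComparison",
    "compare_groups",
    "season_split",
    "BREEDING_MONTHS",
    "significance_mark",
]

#: Default breeding window: April-June.
BREEDING_MONTHS = frozenset({4, 5, 6})


@dataclass(frozen=True)
class GroupComparison:
    """KS and Kruskal-Wallis p-values for one metric/scheme/grouping cell."""

    metric: str  # "f_r" | "r_g" | "S(t)"
    scheme: str  # "ntb" | "np"
    group_a: str
    group_b: str
    testable: bool
    p_ks: float | None = None
    p_kw: float | None = None

    def significant(self, which: str, alpha: float = 0.05) -> bool | None:
        p = {"ks": self.p_ks, "kw": self.p_kw}[which]
        return None if p is None else bool(p < alpha)


def significance_mark(p: float | None) -> str:
    """Grid mark for a p-value: ``✓`` below 0.05, ``*`` below 0.1, else ``—``."""
    if p is None:
        return "n/a"
    if p < 0.05:
        return "✓"
    if p < 0.1:
        return "*"
    return "—"


def compare_groups(
    a,
    b,
    metric: str = "",
    scheme: str = "",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Run KS and Kruskal-Wallis on two samples of metric values.

    Samples with fewer than 2 values on either side are flagged untestable
    (no p-values). Identical samples give KS statistic 0 and no flags.
    """
    a = list(a)
    b = list(b)
    if len(a) < 2 or len(b) < 2:
        return GroupComparison(metric, scheme, labels[0], labels[1], testable=False)
    import math
    import warnings

    ks = stats.ks_2samp(a, b)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            kw = stats.kruskal(a, b)
        p_kw = float(kw.pvalue)
        if math.isnan(p_kw):  # degenerate: every value tied across both groups
            p_kw = 1.0
    except ValueError:
        p_kw = 1.0
    return GroupComparison(
        metric,
        scheme,
        labels[0],
        labels[1],
        testable=True,
        p_ks=float(ks.pvalue),
        p_kw=p_kw,
    )


def season_split(
    months: dict[int, list[float]],
    breeding: frozenset[int] | set[int] = BREEDING_MONTHS,
) -> tuple[list[float], list[float]]:
    """Partition monthly metric values into breeding and non-breeding samples.

    ``months`` maps month number (1-12) to that month's values; values from
    months in ``breeding`` (default April-June) form the first sample, all
    others the second.
    """
    in_season: list[float] = []
    out_season: list[float] = []
    for m, values in sorted(months.items()):
        (in_season if m in breeding else out_season).extend(values)
    return in_season, out_season
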