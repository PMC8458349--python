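"""Sample-level statistics: summaries, Z-scores, Kruskal-Wallis, grouping.

The per-sample (>2C-4C) percentages come from two instruments with
systematically different scales, so values are standardized (Z-scored)
before pooling; group differences are then tested with the tie-corrected
Kruskal-Wallis rank test. Sampling clock times collapse into three diel
periods: morning (06:00), midday (12:00) and night (18:00-00:00).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2, rankdata

from .errors import DegenerateScaleError, FormatError, ValidationError
from .events import SampleRecord


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD (n-1 denominator), extrema. ``sd`` is ``None``
    for a single observation."""

    n: int
    mean: float
    sd: float | None
    minimum: float
    maximum: float


def summarize(values: Sequence[float]) -> SummaryStats:
    """Basic statistics of a collection of reals."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty collection")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return SummaryStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )


def standardize(values: Sequence[float]) -> np.ndarray:
    """Z-scores: (x - mean) / sample SD, order preserved.

    Output has mean 0 and sample SD 1; strictly increasing inputs map to
    strictly increasing outputs.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValidationError("standardization needs at least 2 values")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise DegenerateScaleError("all values identical; SD is zero")
    return (arr - arr.mean()) / sd


#: Diel sampling periods: morning / midday / night.
_PERIOD_OF_TIME = {"06:00": "P1", "12:00": "P2", "18:00": "P3", "00:00": "P3"}


def assign_time_period(time_of_day: str) -> str:
    """Map a clock time (HH:MM) to sampling period P1/P2/P3.

    Exact sampling times are 06:00 -> P1, 12:00 -> P2 and 18:00/00:00 ->
    P3; any other time maps to the nearest of the four on the 24 h clock,
    with a warning.
    """
    try:
        hh, mm = time_of_day.strip().split(":")
        minutes = int(hh) * 60 + int(mm)
        if not (0 <= int(hh) < 24 and 0 <= int(mm) < 60):
            raise ValueError
    except (ValueError, AttributeError):
        raise FormatError(f"unparseable clock time: {time_of_day!r}") from None
    canonical = {"06:00": 360, "12:00": 720, "18:00": 1080, "00:00": 0}
    if time_of_day in canonical and canonical[time_of_day] == minutes:
        return _PERIOD_OF_TIME[time_of_day]
    nearest = min(
        canonical,
        key=lambda t: min((minutes - canonical[t]) % 1440,
                          (canonical[t] - minutes) % 1440),
    )
    warnings.warn(
        f"clock time {time_of_day!r} is not a sampling time; "
        f"using nearest {nearest!r}",
        stacklevel=2,
    )
    return _PERIOD_OF_TIME[nearest]


@dataclass(frozen=True)
class KWResult:
    """Tie-corrected Kruskal-Wallis H, degrees of freedom, p-value."""

    h_statistic: float
    df: int
    p_value: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis test for k >= 2 groups.

    Mid-ranks are assigned over the pooled sample;
    ``H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1)`` is divided by the tie
    correction ``1 - sum(t^3 - t)/(N^3 - N)``; the p-value is the upper
    tail of chi-square with k-1 degrees of freedom. A pooled sample with
    every value identical gives H = 0, p = 1.
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("every group must be non-empty")
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if n_total < k + 1:
        raise ValidationError(f"need at least {k + 1} pooled values, got {n_total}")

    ranks = rankdata(pooled, method="average")
    bounds = np.cumsum(sizes)
    rank_sums = np.array(
        [ranks[lo:hi].sum() for lo, hi in zip(np.r_[0, bounds[:-1]], bounds)]
    )
    h = (12.0 / (n_total * (n_total + 1))) * float(
        np.sum(rank_sums ** 2 / sizes)
    ) - 3.0 * (n_total + 1)

    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts ** 3 - tie_counts)) / (
        n_total ** 3 - n_total
    )
    if correction == 0.0:  # all pooled values identical
        return KWResult(h_statistic=0.0, df=k - 1, p_value=1.0)
    h = max(0.0, h / correction)  # clamp the tiny negative round-off at H ~ 0
    return KWResult(h_statistic=h, df=k - 1,
                    p_value=float(chi2.sf(h, k - 1)))


def kruskal_wallis_permutation_p(
    groups: Sequence[Sequence[float]], max_n: int = 12
) -> float:
    """Exact permutation p-value for tiny samples (pooled n <= ``max_n``).

    Enumerates every assignment of the pooled mid-ranks to groups of the
    observed sizes and reports the fraction with H at least as large as
    observed.
    """
    groups = [list(g) for g in groups]
    sizes = [len(g) for g in groups]
    n_total = sum(sizes)
    if n_total > max_n:
        raise ValidationError(
            f"permutation test limited to pooled n <= {max_n}, got {n_total}"
        )
    observed = kruskal_wallis(groups).h_statistic
    pooled = [v for g in groups for v in g]
    ranks = rankdata(pooled, method="average")

    def _h_from_rank_sums(rank_sums):
        h = (12.0 / (n_total * (n_total + 1))) * sum(
            r * r / s for r, s in zip(rank_sums, sizes)
        ) - 3.0 * (n_total + 1)
        _, t = np.unique(pooled, return_counts=True)
        corr = 1.0 - float(np.sum(t ** 3 - t)) / (n_total ** 3 - n_total)
        return 0.0 if corr == 0.0 else h / corr

    count = total = 0

    def _assign(remaining: tuple[int, ...], g: int, sums: list[float]):
        nonlocal count, total
        if g == len(sizes) - 1:
            sums.append(sum(ranks[i] for i in remaining))
            total += 1
            if _h_from_rank_sums(sums) >= observed - 1e-12:
                count += 1
            sums.pop()
            return
        for chosen in combinations(remaining, sizes[g]):
            rest = tuple(i for i in remaining if i not in chosen)
            sums.append(sum(ranks[i] for i in chosen))
            _assign(rest, g + 1, sums)
            sums.pop()

    _assign(tuple(range(n_total)), 0, [])
    return count / total


# ---------------------------------------------------------------------------
# fixture analysis
# ---------------------------------------------------------------------------

_FACTORS = ("time_period", "treatment", "colony")


@dataclass(frozen=True)
class FixtureAnalysis:
    """Grouped summary + Kruskal-Wallis on standardized (>2C-4C) percent."""

    factor: str
    standardization: str  # "pooled" | "within_method"
    group_stats: Mapping[str, SummaryStats]
    kw: KWResult


def analyze_fixture(
    records: Sequence[SampleRecord],
    factor: str,
    standardization: str = "pooled",
) -> FixtureAnalysis:
    """Test a grouping factor against standardized (>2C-4C) percentages.

    ``standardization="pooled"`` Z-scores all samples together (the
    default; since the rank test is invariant under monotone transforms
    this matches testing the raw percentages). ``"within_method"``
    Z-scores the IFC and sorting arms separately before pooling, removing
    the between-instrument scale difference at the cost of equating the
    two arms' spreads.
    """
    if factor not in _FACTORS:
        raise ValidationError(f"factor must be one of {_FACTORS}, got {factor!r}")
    if standardization not in ("pooled", "within_method"):
        raise ValidationError(f"unknown standardization {standardization!r}")
    records = list(records)
    values = np.array([r.pct_hyper for r in records])
    if standardization == "pooled":
        z = standardize(values)
    else:
        z = np.empty(len(records))
        for arm in sorted({r.analysis_type for r in records}):
            idx = [i for i, r in enumerate(records) if r.analysis_type == arm]
            z[idx] = standardize(values[idx])

    def _level(r: SampleRecord) -> str:
        if factor == "time_period":
            return assign_time_period(r.time_of_day)
        if factor == "treatment":
            return r.treatment
        return r.colony_id

    levels = [_level(r) for r in records]
    unique_levels = sorted(set(levels))
    if len(unique_levels) < 2:
        raise ValidationError(f"factor {factor!r} has a single level")
    grouped = {
        lev: [z[i] for i, l in enumerate(levels) if l == lev]
        for lev in unique_levels
    }
    return FixtureAnalysis(
        factor=factor,
        standardization=standardization,
        group_stats={lev: summarize(vals) for lev, vals in grouped.items()},
        kw=kruskal_wallis(list(grouped.values())),
    )
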