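"""DNA-content gating of cytometry events.

Reconstructs a cell-cycle gating template on the propidium-iodide (PI)
fluorescence axis: the main population peak defines the haploid ``1C``
region; a region of identical width is centred at twice the geometric mean
of the 1C events and named ``2C``; the interval between them is ``S`` phase;
everything above the 2C region, up to the brightest detected event, is the
``(>2C-4C)`` ("hyper") region where meiotic stages accumulate. Upstream of
the histogram the module removes out-of-focus events (low gradient-RMS
focus metric) and coincident-event aggregates (excess area for their
fluorescence).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateGatingError,
    EmptyGateError,
    FeatureMissingError,
    InsufficientDataError,
    ValidationError,
)
from .events import EventSet

#: Conversion between the full width at half maximum of a Gaussian-like
#: peak and its standard deviation.
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Default half-width of the 1C gate in units of the estimated 1C peak SD.
#: Under multiplicative (constant-CV) noise the 2C peak has twice the SD of
#: the 1C peak, and the 2C gate is constrained to the same width as 1C; a
#: half-width of 6 sigma_1C therefore covers +/-3 sigma of the 2C peak.
DEFAULT_WIDTH_SIGMA = 6.0


class GateLabel(str, enum.Enum):
    """DNA-content gate assigned to each retained event."""

    SUB_C1 = "SUB_C1"
    C1 = "C1"
    S = "S"
    C2 = "C2"
    HYPER = "HYPER"
    UNFOCUSED = "UNFOCUSED"
    AGGREGATE = "AGGREGATE"


#: Labels that enter the composition denominator.
GATED_LABELS = (GateLabel.C1, GateLabel.S, GateLabel.C2, GateLabel.HYPER)


@dataclass(frozen=True)
class GateRegions:
    """Interval boundaries of the 1C / S / 2C / hyper gates.

    Invariants (checked on construction):

    * ``0 < c1_low < c1_high <= c2_low < c2_high <= hyper_high``;
    * the 2C region has the same width as the 1C region;
    * the 2C region is centred at ``2 * c1_geometric_mean``.
    """

    c1_low: float
    c1_high: float
    c2_low: float
    c2_high: float
    hyper_high: float
    c1_geometric_mean: float

    def __post_init__(self):
        if not (0 < self.c1_low < self.c1_high <= self.c2_low
                < self.c2_high <= self.hyper_high):
            raise ValidationError(
                "gate boundaries must satisfy 0 < c1_low < c1_high <= c2_low"
                f" < c2_high <= hyper_high; got {self}"
            )
        w1 = self.c1_high - self.c1_low
        w2 = self.c2_high - self.c2_low
        if not math.isclose(w1, w2, rel_tol=1e-9):
            raise ValidationError(f"1C width {w1} != 2C width {w2}")
        center = 0.5 * (self.c2_low + self.c2_high)
        if not math.isclose(center, 2.0 * self.c1_geometric_mean, rel_tol=1e-9):
            raise ValidationError(
                f"2C centre {center} != 2 x geometric mean "
                f"{2 * self.c1_geometric_mean}"
            )


# ---------------------------------------------------------------------------
# focus filtering
# ---------------------------------------------------------------------------

def auto_focus_threshold(values: np.ndarray, n_bins: int = 64,
                         depth_ratio: float = 2.0) -> float:
    """Threshold at the minimum-density valley between the two focus modes.

    A candidate split bin is a genuine between-mode valley when the smaller
    of the two flanking maxima exceeds ``depth_ratio`` times the valley
    density (so a shoulder on a single mode does not qualify). The deepest
    such valley, by that ratio, gives the threshold; if none qualifies the
    distribution is treated as unimodal and the 10th percentile is used.
    """
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=n_bins)
    smoothed = np.convolve(counts.astype(float), np.ones(5) / 5.0, mode="same")
    left_max = np.maximum.accumulate(smoothed)
    right_max = np.maximum.accumulate(smoothed[::-1])[::-1]
    cum = np.cumsum(counts)
    min_mass = max(1.0, 0.01 * counts.sum())  # each mode holds >= 1% of events
    best_i, best_score = None, depth_ratio
    for i in range(1, n_bins - 1):
        if min(cum[i - 1], counts.sum() - cum[i]) < min_mass:
            continue
        flank = min(left_max[i - 1], right_max[i + 1])
        score = flank / max(smoothed[i], 1e-12)
        if score > best_score:
            best_i, best_score = i, score
    if best_i is not None:
        return 0.5 * (edges[best_i] + edges[best_i + 1])
    return float(np.percentile(values, 10.0))


def filter_focused(events: EventSet, threshold: float | str = "auto"):
    """Partition events into (focused, unfocused) by the focus metric.

    Focused events have ``focus_metric >= threshold``. ``"auto"`` places the
    threshold at the valley between the two modes of the focus-metric
    distribution (unfocused cells have systematically lower gradient RMS),
    falling back to the 10th percentile for unimodal data.
    """
    metric = events.table["focus_metric"]
    if metric.isna().any():
        raise FeatureMissingError("focus_metric is absent for some events")
    if threshold == "auto":
        threshold = auto_focus_threshold(metric.to_numpy())
    keep = metric.to_numpy(dtype=float) >= float(threshold)
    return events.subset(keep), events.subset(~keep)


# ---------------------------------------------------------------------------
# singlet / aggregate discrimination
# ---------------------------------------------------------------------------

def filter_singlets(events: EventSet, residual_cutoff: float = 3.0):
    """Partition events into (singlets, aggregates) on the area-fluorescence trend.

    Coincident events (two cells measured as one) carry roughly the summed
    area and fluorescence of their components and therefore sit above the
    singlet trend of cell area against DNA fluorescence. The trend is a
    robust straight line on log-log axes: its slope is the median pairwise
    slope over point pairs whose fluorescence differs by at least 1.5x
    (pairs spanning genuinely different DNA contents; within a single ploidy
    peak both axes vary only by independent measurement noise and carry no
    slope information), and its intercept the median residual offset.
    Events whose area residual, scaled by the median absolute deviation of
    the residuals, exceeds ``residual_cutoff`` on the high-area side are
    labelled aggregates.
    """
    if residual_cutoff <= 0:
        raise ValidationError("residual_cutoff must be positive")
    if len(events) < 20:
        raise InsufficientDataError(
            f"singlet fit needs >= 20 events, got {len(events)}"
        )
    x = np.log(events.table["dna_fluorescence"].to_numpy(dtype=float))
    y = np.log(events.table["cell_area"].to_numpy(dtype=float))

    slope = _robust_span_slope(x, y)
    resid = y - slope * x
    intercept = float(np.median(resid))
    resid -= intercept
    scale = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if scale == 0.0:
        # exact-trend data: anything measurably off the line is an outlier
        scale = 1e-9 * max(1.0, float(np.median(np.abs(y))) or 1.0)
    flagged = resid / scale > residual_cutoff
    return events.subset(~flagged), events.subset(flagged)


def _robust_span_slope(x: np.ndarray, y: np.ndarray,
                       min_log_span: float = math.log(1.5),
                       max_points: int = 1000) -> float:
    """Median slope over point pairs spanning ``min_log_span`` in x.

    Deterministic: points are strided in x-sorted order before the pairwise
    scan, capping the cost at ``max_points**2 / 2`` slope evaluations.
    """
    order = np.argsort(x, kind="stable")
    stride = max(1, len(x) // max_points)
    xs, ys = x[order][::stride], y[order][::stride]
    dx = xs[None, :] - xs[:, None]
    mask = dx >= min_log_span  # upper triangle only, by sort order
    if not mask.any():
        return 0.0
    dy = ys[None, :] - ys[:, None]
    return float(np.median(dy[mask] / dx[mask]))


# ---------------------------------------------------------------------------
# peak finding and region delineation
# ---------------------------------------------------------------------------

def find_c1_peak(fluorescence: Sequence[float], n_bins: int = 256) -> float:
    """Locate the main (1C) peak of a linear-scale fluorescence histogram.

    Returns the centre of the highest-count bin over ``[0, max]``, refined
    by a quadratic fit through the bin and its two neighbours. Ties between
    equal-count bins resolve toward lower fluorescence (the lowest DNA
    content is the main population). When the peak is an isolated spike
    (both neighbours empty) the quadratic carries no information and the
    mean of the in-bin values is returned instead, which is exact for
    noise-free data.
    """
    values = np.asarray(fluorescence, dtype=float)
    if values.size < 100:
        raise InsufficientDataError(
            f"peak detection needs >= 100 values, got {values.size}"
        )
    if values.min() == values.max():
        return float(values[0])
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, values.max()))
    i = int(np.argmax(counts))  # first maximum = lowest-fluorescence tie
    center = 0.5 * (edges[i] + edges[i + 1])
    left = counts[i - 1] if i > 0 else 0
    right = counts[i + 1] if i + 1 < n_bins else 0
    if left == 0 and right == 0:
        inside = (values >= edges[i]) & (values < edges[i + 1])
        if i == n_bins - 1:
            inside = (values >= edges[i]) & (values <= edges[i + 1])
        return float(values[inside].mean())
    denom = left - 2.0 * counts[i] + right
    if denom == 0:
        return center
    offset = 0.5 * (left - right) / denom
    return float(center + offset * (edges[1] - edges[0]))


def _smoothed_histogram(values: np.ndarray, n_bins: int):
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, values.max()))
    smoothed = np.convolve(counts.astype(float), np.ones(3) / 3.0, mode="same")
    return smoothed, edges


def _fwhm(smoothed: np.ndarray, edges: np.ndarray, peak: float) -> float:
    """Full width at half maximum of the peak containing ``peak``."""
    binw = edges[1] - edges[0]
    i = int(np.clip((peak - edges[0]) // binw, 0, len(smoothed) - 1))
    # snap to the local maximum around the nominal peak bin
    lo, hi = max(0, i - 2), min(len(smoothed), i + 3)
    i = lo + int(np.argmax(smoothed[lo:hi]))
    half = smoothed[i] / 2.0

    def _cross(direction: int) -> float | None:
        j = i
        while 0 <= j + direction < len(smoothed):
            if smoothed[j + direction] < half:
                # linear interpolation between bin centres j and j+direction
                c0 = edges[j] + 0.5 * binw
                frac = (smoothed[j] - half) / (smoothed[j] - smoothed[j + direction])
                return abs(frac * binw) + abs(c0 - (edges[i] + 0.5 * binw))
            j += direction
        return None

    left, right = _cross(-1), _cross(+1)
    if left is None and right is None:
        return binw  # flat histogram; nominal one-bin width
    if left is None:
        left = right
    if right is None:
        right = left
    return left + right


def delineate_regions(
    fluorescence: Sequence[float],
    peak: float,
    n_bins: int = 256,
    width: float | None = None,
    width_sigma: float = DEFAULT_WIDTH_SIGMA,
) -> GateRegions:
    """Build the 1C / S / 2C / hyper gate template around the 1C peak.

    The 1C region is ``[peak - w, peak + w]``. By default ``w`` is
    ``width_sigma`` times the 1C peak SD estimated from the full width at
    half maximum of the 3-bin-smoothed histogram; pass ``width`` to force
    ``w`` directly. The 2C region has identical width and is centred at
    twice the geometric mean of the events inside the 1C region; S is the
    open interval between them; the hyper region extends from the end of 2C
    to the brightest detected event.
    """
    values = np.asarray(fluorescence, dtype=float)
    if values.size == 0 or np.any(values <= 0):
        raise ValidationError("fluorescence values must be positive")
    if width is not None:
        w = float(width)
    else:
        smoothed, edges = _smoothed_histogram(values, n_bins)
        w = width_sigma * _fwhm(smoothed, edges, peak) / _FWHM_TO_SIGMA
    if w <= 0:
        raise DegenerateGatingError(f"non-positive 1C half-width {w}")

    c1_low, c1_high = peak - w, peak + w
    if c1_low <= 0:
        raise DegenerateGatingError(
            f"1C region [{c1_low}, {c1_high}] extends below zero"
        )
    in_c1 = (values >= c1_low) & (values < c1_high)
    if not in_c1.any():
        raise DegenerateGatingError("no events inside the 1C region")
    gm = float(np.exp(np.mean(np.log(values[in_c1]))))
    c2_low, c2_high = 2.0 * gm - w, 2.0 * gm + w
    if c2_low < c1_high:
        raise DegenerateGatingError(
            f"2C region [{c2_low}, {c2_high}] overlaps 1C region "
            f"[{c1_low}, {c1_high}]"
        )
    hyper_high = max(float(values.max()), c2_high)
    return GateRegions(c1_low, c1_high, c2_low, c2_high, hyper_high, gm)


# ---------------------------------------------------------------------------
# gate assignment and composition
# ---------------------------------------------------------------------------

def assign_gates(events: EventSet, regions: GateRegions) -> EventSet:
    """Label every event with its DNA-content gate.

    Intervals are half-open ``[low, high)`` except the hyper region, whose
    upper endpoint is closed so that the brightest detected event is gated.
    Returns a new :class:`EventSet` with a ``gate`` column.
    """
    f = events.table["dna_fluorescence"].to_numpy(dtype=float)
    labels = np.select(
        [
            f < regions.c1_low,
            f < regions.c1_high,
            f < regions.c2_low,
            f < regions.c2_high,
        ],
        [GateLabel.SUB_C1.value, GateLabel.C1.value,
         GateLabel.S.value, GateLabel.C2.value],
        default=GateLabel.HYPER.value,
    )
    out = events.copy()
    out.table["gate"] = labels
    return out


@dataclass(frozen=True)
class GateComposition:
    """Percentages of the gated population in each DNA-content class."""

    pct_c1_plus_s: float
    pct_c2: float
    pct_hyper: float
    n_gated: int

    def rounded(self, ndigits: int = 1):
        """Percentages at the precision conventionally reported."""
        return (round(self.pct_c1_plus_s, ndigits),
                round(self.pct_c2, ndigits),
                round(self.pct_hyper, ndigits))


def gate_composition(labeled: EventSet) -> GateComposition:
    """Percent of gated events in 1C+S, 2C and the hyper region.

    The denominator counts only C1, S, C2 and HYPER events; sub-1C debris
    and filtered artifacts are excluded, mirroring how per-sample DNA
    content tables are reported.
    """
    if "gate" not in labeled.table.columns:
        raise ValidationError("events carry no gate labels; run assign_gates")
    gate = labeled.table["gate"]
    n = {lab: int((gate == lab.value).sum()) for lab in GateLabel}
    denom = sum(n[lab] for lab in GATED_LABELS)
    if denom == 0:
        raise EmptyGateError("no events in the gated denominator")
    pct = lambda c: 100.0 * c / denom
    return GateComposition(
        pct_c1_plus_s=pct(n[GateLabel.C1] + n[GateLabel.S]),
        pct_c2=pct(n[GateLabel.C2]),
        pct_hyper=pct(n[GateLabel.HYPER]),
        n_gated=denom,
    )
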