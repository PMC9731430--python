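"""Per-cell trace feature extraction.

Each cell's three-channel intensity trace is condensed into a *fingerprint*:

* calcium-transient-style **peaks** — local maxima selected by topographic
  prominence and filtered by their half-prominence width-to-prominence
  ratio, so extremely broad humps are not mistaken for transients;
* **changepoints** — frames where the best penalized piecewise-linear fit
  of the trace changes segment, with a slope-difference filter that
  discards kinks indistinguishable from baseline drift;
* basic summary statistics (min, max, argmax, mean, variance, range,
  mean after a reference frame, range after the maximum).

The fingerprint is the sole input of the rule-based behavior classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

if TYPE_CHECKING:  # pragma: no cover
    from .intensity import IntensityTrace


# ---------------------------------------------------------------------------
# parameters


@dataclass
class PeakParams:
    """Transient (peak) detection settings.

    ``min_prominence`` is in background-subtracted intensity units; the
    width measure is the half-prominence width in frames.  Peaks whose
    width/prominence ratio exceeds ``max_width_prominence_ratio`` are
    rejected as too broad to be transients.
    """

    min_prominence: float = 3.0
    max_width_prominence_ratio: float = 10.0

    def __post_init__(self) -> None:
        if self.min_prominence <= 0 or self.max_width_prominence_ratio <= 0:
            raise ValueError("peak parameters must be positive")


@dataclass
class StepParams:
    """Changepoint (intensity step) detection settings.

    ``penalty`` is the model-selection constant added per extra linear
    segment (units of squared intensity); it is calibrated once so that a
    single ideal step yields at most ``max_changepoints_per_step``
    changepoints, and is never tuned per trace.  Changepoints whose
    bracketing segment slopes differ by less than ``min_slope_difference``
    (a.u./frame) are discarded as baseline drift.
    """

    penalty: float = 25.0
    max_changepoints_per_step: int = 2
    min_slope_difference: float = 0.1
    min_level_jump: float = 1.0
    min_segment_length: int = 10

    def __post_init__(self) -> None:
        if (
            self.penalty <= 0
            or self.min_slope_difference <= 0
            or self.min_level_jump <= 0
            or self.min_segment_length <= 0
            or self.max_changepoints_per_step <= 0
        ):
            raise ValueError("step parameters must be positive")


# ---------------------------------------------------------------------------
# result containers


@dataclass
class Peak:
    location: int
    height: float
    prominence: float
    width: float


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __bool__(self) -> bool:
        return bool(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def locations(self) -> np.ndarray:
        return np.array([p.location for p in self.peaks], dtype=int)

    @property
    def first_location(self) -> int | None:
        return self.peaks[0].location if self.peaks else None


@dataclass
class Changepoint:
    index: int
    pre_slope: float
    post_slope: float
    level_jump: float = 0.0


@dataclass
class ChangepointSet:
    changepoints: list[Changepoint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.changepoints)

    def __bool__(self) -> bool:
        return bool(self.changepoints)

    def __iter__(self):
        return iter(self.changepoints)

    @property
    def indices(self) -> np.ndarray:
        return np.array([c.index for c in self.changepoints], dtype=int)

    @property
    def first_index(self) -> int | None:
        return self.changepoints[0].index if self.changepoints else None


@dataclass
class TraceStats:
    """Summary statistics of a single-channel trace."""

    min: float
    max: float
    argmax: int
    mean: float
    variance: float
    range: float
    mean_after: dict[int, float]
    range_after_argmax: float


@dataclass
class FeatureFingerprint:
    """All extracted features of one cell, input to the decision tree."""

    cell_id: int
    stats: dict[str, TraceStats]
    peaks: dict[str, PeakSet]
    changepoints: dict[str, ChangepointSet]
    red_blue_mean_diff: float


# ---------------------------------------------------------------------------
# operations


def find_transients(trace: np.ndarray, params: PeakParams | None = None) -> PeakSet:
    """Detect transient-like peaks in a trace.

    A sample is a peak if its topographic prominence is at least
    ``min_prominence`` and its half-prominence width divided by its
    prominence does not exceed ``max_width_prominence_ratio``.  Peaks are
    returned in increasing frame order.
    """
    params = params or PeakParams()
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        return PeakSet()
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    locs, props = find_peaks(
        trace,
        prominence=params.min_prominence,
        width=0,
        rel_height=0.5,  # width measured at half prominence
    )
    peaks = []
    for loc, prom, width in zip(locs, props["prominences"], props["widths"]):
        if width / prom <= params.max_width_prominence_ratio:
            peaks.append(Peak(int(loc), float(trace[loc]), float(prom), float(width)))
    return PeakSet(peaks)


def _segment_costs(trace: np.ndarray, min_len: int) -> tuple[np.ndarray, ...]:
    """Cumulative sums enabling O(1) least-squares line cost per segment."""
    t = np.arange(trace.size, dtype=float)
    z = np.zeros(1)
    c1 = np.concatenate([z, np.cumsum(np.ones_like(t))])
    ct = np.concatenate([z, np.cumsum(t)])
    ctt = np.concatenate([z, np.cumsum(t * t)])
    cy = np.concatenate([z, np.cumsum(trace)])
    cty = np.concatenate([z, np.cumsum(t * trace)])
    cyy = np.concatenate([z, np.cumsum(trace * trace)])
    return c1, ct, ctt, cy, cty, cyy


def _line_sse(cums, i: np.ndarray, j: int) -> np.ndarray:
    """SSE of the least-squares line over [i, j) for an array of starts i."""
    c1, ct, ctt, cy, cty, cyy = cums
    n = c1[j] - c1[i]
    sx = ct[j] - ct[i]
    sxx = ctt[j] - ctt[i]
    sy = cy[j] - cy[i]
    sxy = cty[j] - cty[i]
    syy = cyy[j] - cyy[i]
    det = n * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(det > 0, (n * sxy - sx * sy) / np.where(det > 0, det, 1.0), 0.0)
        intercept = (sy - slope * sx) / n
    sse = syy - intercept * sy - slope * sxy
    return np.maximum(sse, 0.0)


def _segment_fit(cums, i: int, j: int) -> tuple[float, float]:
    """Least-squares (slope, intercept) of the line over [i, j)."""
    c1, ct, ctt, cy, cty, _ = cums
    n = c1[j] - c1[i]
    sx = ct[j] - ct[i]
    sxx = ctt[j] - ctt[i]
    sy = cy[j] - cy[i]
    sxy = cty[j] - cty[i]
    det = n * sxx - sx * sx
    if det <= 0:
        return 0.0, float(sy / n) if n else 0.0
    slope = float((n * sxy - sx * sy) / det)
    return slope, float((sy - slope * sx) / n)


def find_steps(trace: np.ndarray, params: StepParams | None = None) -> ChangepointSet:
    """Detect intensity-step changepoints by penalized piecewise-linear fit.

    The trace is segmented by exact dynamic programming minimizing
    ``sum(segment SSE) + penalty * (number of changepoints)`` over all
    segmentations with segments of at least ``min_segment_length`` frames.
    Each changepoint index is the first frame of the new segment.
    A changepoint is kept only when it marks a genuine step rather than
    baseline drift: either the bracketing fitted slopes differ by at
    least ``min_slope_difference`` or the fitted levels are discontinuous
    at the boundary by at least ``min_level_jump`` (a raw level shift has
    equal slopes on both sides yet is still a step).  Reported pre/post
    slopes are those of the originally fitted segments.
    """
    params = params or StepParams()
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    m = params.min_segment_length
    if n < 2 * m:
        raise ValueError(f"trace length {n} < 2 * min_segment_length {m}")
    cums = _segment_costs(trace, m)

    best = np.full(n + 1, np.inf)
    best[0] = -params.penalty  # first segment carries no penalty
    prev = np.zeros(n + 1, dtype=int)
    for j in range(m, n + 1):
        starts = np.arange(0, j - m + 1)
        # segments must end at n or leave room for another of length >= m
        cand = best[starts] + params.penalty + _line_sse(cums, starts, j)
        k = int(np.argmin(cand))
        best[j] = cand[k]
        prev[j] = starts[k]

    bounds = [n]
    j = n
    while j > 0:
        j = int(prev[j])
        bounds.append(j)
    bounds.reverse()  # 0, cp1, cp2, ..., n

    fits = [
        _segment_fit(cums, bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)
    ]
    cps = []
    for k in range(1, len(bounds) - 1):
        (pre, b_pre), (post, b_post) = fits[k - 1], fits[k]
        at = float(bounds[k])
        jump = (post * at + b_post) - (pre * at + b_pre)
        if (
            abs(post - pre) >= params.min_slope_difference
            or abs(jump) >= params.min_level_jump
        ):
            cps.append(Changepoint(int(bounds[k]), pre, post, float(jump)))
    return ChangepointSet(cps)


def summarize(trace: np.ndarray, after_frames: Iterable[int] = ()) -> TraceStats:
    """Exact summary statistics of a trace.

    ``mean_after[f]`` is the mean over frames strictly greater than ``f``;
    ``range_after_argmax`` is max minus min over frames at or after the
    (first) maximum.  Variance is the population variance.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    amax = int(np.argmax(trace))
    tail = trace[amax:]
    mean_after = {}
    for f in after_frames:
        seg = trace[f + 1:]
        mean_after[int(f)] = float(np.mean(seg)) if seg.size else float("nan")
    return TraceStats(
        min=float(trace.min()),
        max=float(trace.max()),
        argmax=amax,
        mean=float(trace.mean()),
        variance=float(trace.var()),
        range=float(trace.max() - trace.min()),
        mean_after=mean_after,
        range_after_argmax=float(tail.max() - tail.min()),
    )


def fingerprint(
    trace: "IntensityTrace",
    peak_params: PeakParams | None = None,
    step_params: StepParams | None = None,
    after_frames: Sequence[int] = (50,),
) -> FeatureFingerprint:
    """Extract the full feature fingerprint of one cell.

    Peaks are computed on the green and blue channels, changepoints on the
    blue and green channels, summary statistics on all three, plus the
    cross-channel mean red-minus-blue difference.  The trace must already
    be background subtracted (and smoothed per pipeline configuration).
    """
    if not trace.background_subtracted:
        raise ValueError(
            "fingerprint requires background-subtracted traces "
            "(run background subtraction before extraction)"
        )
    peak_params = peak_params or PeakParams()
    step_params = step_params or StepParams()
    channels = {"blue": trace.blue, "green": trace.green, "red": trace.red}
    stats = {name: summarize(v, after_frames) for name, v in channels.items()}
    peaks = {
        "blue": find_transients(channels["blue"], peak_params),
        "green": find_transients(channels["green"], peak_params),
    }
    changepoints = {
        "blue": find_steps(channels["blue"], step_params),
        "green": find_steps(channels["green"], step_params),
    }
    diff = float(np.mean(channels["red"] - channels["blue"]))
    return FeatureFingerprint(
        cell_id=trace.cell_id,
        stats=stats,
        peaks=peaks,
        changepoints=changepoints,
        red_blue_mean_diff=diff,
    )
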