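"""Moving-window drowsiness metrics and cross-device agreement.

PERCLOS and blink rate are computed over a 1-minute moving window advanced
in 0.1 s steps.  A blink is counted in a window when its minimum falls
inside it; the "closure" period of a blink is approximated as 20% of its
duration, centred on the minimum, and PERCLOS is the percentage of a window
occupied by closure.  Two recordings are aligned via the extended eyes-
closed epoch placed at the start of a session, and cross-device similarity
is quantified with the Pearson correlation of the paired metric series plus
a greedy one-to-one blink matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ocular_signal import BlinkEvent, TimeSeries

__all__ = [
    "MetricSeries",
    "blink_rate_series",
    "perclos_series",
    "perclos_area_threshold",
    "align_recordings",
    "correlate_metrics",
    "detection_agreement",
]


@dataclass
class MetricSeries:
    """A drowsiness metric sampled on a moving-window grid.

    ``window_centers`` advance in fixed steps (0.1 s by default); ``values``
    are PERCLOS in percent or blink rate in blinks/min.
    """

    window_centers: np.ndarray
    values: np.ndarray
    window_s: float = 60.0
    name: str = ""

    def __post_init__(self) -> None:
        self.window_centers = np.asarray(self.window_centers, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.window_centers) != len(self.values):
            raise ValueError("centers and values must have equal length")
        if len(self.window_centers) > 1 and not (np.diff(self.window_centers) > 0).all():
            raise ValueError("window centers must be strictly increasing")


def _window_centers(t_start: float, t_end: float, window_s: float, step_s: float) -> np.ndarray:
    """Centers of all full windows inside [t_start, t_end], step ``step_s``.

    Yields exactly floor((T - window) / step) + 1 windows for span T;
    partial windows at the recording edges are dropped.
    """
    span = t_end - t_start
    if span < window_s:
        raise ValueError(
            f"recording ({span:.1f} s) shorter than one {window_s:.0f} s window"
        )
    n = int(np.floor((span - window_s) / step_s + 1e-9)) + 1
    return t_start + window_s / 2.0 + np.arange(n) * step_s


def blink_rate_series(
    events: list[BlinkEvent],
    t_start: float,
    t_end: float,
    window_s: float = 60.0,
    step_s: float = 0.1,
) -> MetricSeries:
    """Blinks per minute in each moving window.

    A blink belongs to the window when its minimum time falls in
    [center - w/2, center + w/2); the count is scaled to blinks/min.
    """
    centers = _window_centers(t_start, t_end, window_s, step_s)
    mins = np.sort(np.array([e.min_s for e in events], dtype=np.float64))
    lo = np.searchsorted(mins, centers - window_s / 2.0, side="left")
    hi = np.searchsorted(mins, centers + window_s / 2.0, side="left")
    values = (hi - lo) * (60.0 / window_s)
    return MetricSeries(centers, values.astype(np.float64), window_s, name="blink_rate")


def _closure_intervals(events: list[BlinkEvent], closure_fraction: float) -> list[tuple[float, float]]:
    """Per-blink closure intervals (fraction of duration centred on the
    minimum), merged into a disjoint union."""
    raw = sorted(
        (
            (e.min_s - closure_fraction * e.duration / 2.0, e.min_s + closure_fraction * e.duration / 2.0)
            for e in events
        )
    )
    merged: list[tuple[float, float]] = []
    for a, b in raw:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def perclos_series(
    events: list[BlinkEvent],
    t_start: float,
    t_end: float,
    closure_fraction: float = 0.2,
    window_s: float = 60.0,
    step_s: float = 0.1,
) -> MetricSeries:
    """PERCLOS (%) in each moving window.

    Each blink contributes a closure interval of ``closure_fraction`` times
    its duration centred at the minimum; PERCLOS is 100 × the closure time
    intersecting the window divided by the window length.
    """
    if not 0.0 < closure_fraction <= 1.0:
        raise ValueError("closure_fraction must be in (0, 1]")
    centers = _window_centers(t_start, t_end, window_s, step_s)
    intervals = _closure_intervals(events, closure_fraction)
    values = np.zeros(len(centers))
    for a, b in intervals:
        w_lo = centers - window_s / 2.0
        w_hi = centers + window_s / 2.0
        overlap = np.clip(np.minimum(b, w_hi) - np.maximum(a, w_lo), 0.0, None)
        values += overlap
    values = 100.0 * values / window_s
    return MetricSeries(centers, values, window_s, name="perclos")


def perclos_area_threshold(
    s: TimeSeries,
    threshold_fraction: float = 0.2,
    baseline_window_s: float = 30.0,
    window_s: float = 60.0,
    step_s: float = 0.1,
) -> MetricSeries:
    """Alternative PERCLOS straight from the area signal.

    A sample counts as "closed" when the eye area is below
    ``threshold_fraction`` of a rolling open-eye baseline (a rolling
    high-percentile of the signal).  Provided for comparison with the
    blink-duration surrogate; the surrogate is the primary definition.
    """
    t, v = s.times, s.values
    half = max(1, int(round(baseline_window_s * (s.nominal_rate or 30.0) / 2)))
    baseline = np.empty(len(v))
    for i in range(len(v)):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        baseline[i] = np.percentile(v[lo:hi], 90)
    closed = v < threshold_fraction * baseline
    centers = _window_centers(float(t[0]), float(t[-1]), window_s, step_s)
    values = np.empty(len(centers))
    for k, c in enumerate(centers):
        m = (t >= c - window_s / 2.0) & (t < c + window_s / 2.0)
        values[k] = 100.0 * closed[m].mean() if m.any() else 0.0
    return MetricSeries(centers, values, window_s, name="perclos_area")


# ---------------------------------------------------------------------------
# Cross-device alignment and agreement
# ---------------------------------------------------------------------------


def _closure_end_time(s: TimeSeries, low_frac: float = 0.5, open_frac: float = 0.9) -> float:
    """End of the initial eyes-closed epoch of a recording.

    The baseline is the 95th percentile of the (valid) signal; the initial
    closure is the run of samples below ``low_frac`` × baseline starting at
    the first sample, and its end is the linearly interpolated time at which
    the signal first recovers to ``open_frac`` × baseline.  Invalid samples
    (the pupil tracker's missing data) count as closed.
    """
    t = s.times
    v = s.values.astype(np.float64).copy()
    v[~s.valid] = 0.0
    baseline = float(np.percentile(v[s.valid], 95)) if s.valid.any() else 0.0
    if baseline <= 0:
        raise ValueError("signal has no open-eye baseline")
    low = v < low_frac * baseline
    if not low[0]:
        raise ValueError("recording does not start with a closure epoch")
    i = 0
    while i < len(v) and low[i]:
        i += 1
    if i >= len(v):
        raise ValueError("signal never reopens after the initial closure")
    # first crossing of the open threshold after the low run
    thr = open_frac * baseline
    j = i
    while j < len(v) and v[j] < thr:
        j += 1
    if j >= len(v):
        raise ValueError("signal never reaches the open baseline")
    if j == 0 or v[j] == v[j - 1]:
        return float(t[j])
    # linear interpolation for sub-sample timing
    frac = (thr - v[j - 1]) / (v[j] - v[j - 1])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def align_recordings(a: TimeSeries, b: TimeSeries) -> float:
    """Clock offset between two recordings sharing an initial closure epoch.

    Both signals must begin with an extended eyes-closed period (the
    alignment epoch recorded at the start of a session).  Returns the offset
    in seconds such that ``b_time + offset`` is on ``a``'s clock.
    """
    return _closure_end_time(a) - _closure_end_time(b)


def correlate_metrics(a: MetricSeries, b: MetricSeries, max_gap_s: float = 0.05) -> float:
    """Pearson correlation of two metric series paired by window centre.

    Values are paired by nearest centre within ``max_gap_s``.  Raises when
    fewer than 3 pairs exist or either series has zero variance.
    """
    idx = np.searchsorted(b.window_centers, a.window_centers)
    pairs_a, pairs_b = [], []
    for k, c in enumerate(a.window_centers):
        best, best_gap = -1, np.inf
        for j in (idx[k] - 1, idx[k]):
            if 0 <= j < len(b.window_centers):
                gap = abs(b.window_centers[j] - c)
                if gap < best_gap:
                    best, best_gap = j, gap
        if best >= 0 and best_gap <= max_gap_s:
            pairs_a.append(a.values[k])
            pairs_b.append(b.values[best])
    if len(pairs_a) < 3:
        raise ValueError("fewer than 3 paired metric values")
    pa, pb = np.asarray(pairs_a), np.asarray(pairs_b)
    if pa.std() == 0 or pb.std() == 0:
        raise ValueError("zero variance in a metric series")
    return float(stats.pearsonr(pa, pb)[0])


def _overlap(x: BlinkEvent, y: BlinkEvent) -> float:
    return max(0.0, min(x.end_s, y.end_s) - max(x.start_s, y.start_s))


def detection_agreement(
    events_a: list[BlinkEvent],
    events_b: list[BlinkEvent],
    overlap_rule: str = "any",
) -> tuple[float | None, list[tuple[int, int]]]:
    """Fraction of reference blinks (``events_b``) matched by ``events_a``.

    Greedy one-to-one matching: reference events are taken in order and each
    claims the unmatched candidate event with the largest temporal overlap.
    ``overlap_rule`` "any" accepts any positive overlap; "majority" requires
    the overlap to cover at least half of the reference event.  Returns the
    matched fraction (None when the reference list is empty) and the matched
    (a_index, b_index) pairs.
    """
    if overlap_rule not in ("any", "majority"):
        raise ValueError("overlap_rule must be 'any' or 'majority'")
    if not events_b:
        return None, []
    used = set()
    matches: list[tuple[int, int]] = []
    for j, ref in enumerate(events_b):
        best, best_ov = -1, 0.0
        for i, ev in enumerate(events_a):
            if i in used:
                continue
            ov = _overlap(ev, ref)
            if ov > best_ov:
                best, best_ov = i, ov
        if best < 0:
            continue
        if overlap_rule == "majority" and best_ov < 0.5 * (ref.end_s - ref.start_s):
            continue
        used.add(best)
        matches.append((best, j))
    return len(matches) / len(events_b), matches
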