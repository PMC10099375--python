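"""Ocular time-series processing: eye area, EAR, and blink detection.

The wearable glass streams an eye-open-area signal at ~30 Hz computed from
the six eyelid keypoints; a video eye tracker of the EyeLink kind reports
pupil area at ~500 Hz and simply drops samples while the pupil is occluded.
This module converts keypoints to the area signal and reconstructs blink
events from either signal:

* the glass (area) detector up-samples the signal, finds qualified local
  minima and scans outward for the "stable points" where the signal stops
  increasing — these are the blink start and end;
* the pupil detector takes each missing-sample run and extends it backward
  and forward to the same kind of stable point, recovering the true extent
  of the eyelid movement, which starts well before and ends well after the
  pupil disappears.

Stable-point rule used by both detectors: scanning away from the blink, the
signal has stopped increasing once ``plateau_len`` consecutive one-sample
differences are non-positive; the boundary is placed at the sample of that
plateau nearest the blink.  Single-sample tests are fragile under noise,
hence the run requirement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lgn import KeypointSet

__all__ = [
    "TimeSeries",
    "BlinkEvent",
    "eye_area_from_keypoints",
    "eye_aspect_ratio",
    "upsample_series",
    "detect_blinks_area",
    "detect_blinks_pupil",
    "filter_blinks",
]

# polygon vertex order for the area hexagon:
# temporal corner -> upper lid (x2) -> nasal corner -> lower lid (x2)
_HEX_ORDER = (0, 2, 3, 1, 5, 4)


@dataclass
class TimeSeries:
    """A timestamped, validity-masked 1-D signal (eye area or pupil area).

    ``times`` are seconds and must be strictly increasing; ``values`` are
    px² and must be non-negative wherever ``valid`` is True.
    """

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    nominal_rate: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.valid is None:
            self.valid = np.ones(len(self.times), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.valid)):
            raise ValueError("times, values and valid must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if np.any(self.values[self.valid] < 0):
            raise ValueError("values must be non-negative where valid")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class BlinkEvent:
    """One detected blink: eyelid excursion start, minimum, and end times."""

    start_s: float
    min_s: float
    end_s: float
    source: str = "glass"  # "glass" | "pupil" | "truth"

    def __post_init__(self) -> None:
        if not (self.start_s < self.min_s < self.end_s):
            raise ValueError(
                f"blink times must satisfy start < min < end, got "
                f"({self.start_s}, {self.min_s}, {self.end_s})"
            )

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# Keypoints -> scalar eye-state measures
# ---------------------------------------------------------------------------


def eye_area_from_keypoints(kps: KeypointSet | np.ndarray) -> float:
    """Open-eye area: absolute shoelace area of the keypoint hexagon, px².

    The hexagon runs temporal corner -> upper-lid points -> nasal corner ->
    lower-lid points.  An invalid or non-finite keypoint yields NaN so the
    caller can flag the sample invalid.
    """
    if isinstance(kps, KeypointSet):
        if not kps.all_valid:
            return float("nan")
        pts = kps.points
    else:
        pts = np.asarray(kps, dtype=np.float64)
        if pts.shape != (6, 2):
            raise ValueError("expected 6 (row, col) keypoints")
    if not np.isfinite(pts).all():
        return float("nan")
    poly = pts[list(_HEX_ORDER)]
    r, c = poly[:, 0], poly[:, 1]
    area2 = np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1))
    return float(abs(area2) / 2.0)


def eye_aspect_ratio(kps: KeypointSet | np.ndarray) -> float:
    """Eye aspect ratio (EAR): mean lid separation over corner-to-corner width.

    The two upper-lid points are paired with the two lower-lid points; the
    mean of the two separations is divided by the corner distance.  Raises on
    coincident corners (zero width).
    """
    pts = kps.points if isinstance(kps, KeypointSet) else np.asarray(kps, dtype=np.float64)
    if pts.shape != (6, 2):
        raise ValueError("expected 6 (row, col) keypoints")
    width = float(np.hypot(*(pts[1] - pts[0])))
    if width == 0.0:
        raise ValueError("corner points coincide: zero eye width")
    sep = (np.hypot(*(pts[2] - pts[4])) + np.hypot(*(pts[3] - pts[5]))) / 2.0
    return float(sep / width)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def upsample_series(s: TimeSeries, target_rate: float = 250.0) -> TimeSeries:
    """Linearly interpolate a series onto a uniform grid at ``target_rate`` Hz.

    The grid spans the original time range starting at the first sample;
    invalid samples are bridged linearly from their valid neighbours.
    Requires at least two valid samples.
    """
    if int(s.valid.sum()) < 2:
        raise ValueError("need at least two valid samples to upsample")
    t0, t1 = s.t_start, s.t_end
    n = int(np.floor((t1 - t0) * target_rate)) + 1
    grid = t0 + np.arange(n) / target_rate
    tv = s.times[s.valid]
    vv = s.values[s.valid]
    out = np.interp(grid, tv, vv)
    return TimeSeries(grid, out, np.ones(n, dtype=bool), nominal_rate=target_rate)


# ---------------------------------------------------------------------------
# Blink detection — glass eye-area signal
# ---------------------------------------------------------------------------


def _bridge_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid samples by linear interpolation between valid ones."""
    if valid.all():
        return values.astype(np.float64)
    if not valid.any():
        raise ValueError("series has no valid samples")
    idx = np.arange(len(values), dtype=np.float64)
    return np.interp(idx, idx[valid], values[valid])


def _rolling_median(v: np.ndarray, half: int) -> np.ndarray:
    """Centred rolling median (window 2*half+1, edges replicate-padded)."""
    from scipy.ndimage import median_filter

    return median_filter(v.astype(np.float64), size=2 * half + 1, mode="nearest")


def _scan_backward(
    v: np.ndarray, i: int, lo: int, plateau_len: int, arm_level: float = -np.inf
) -> int:
    """Backward stable-point scan from minimum index ``i`` down to ``lo``.

    Returns the index of the sample nearest the minimum at which the
    backward-scanned signal has stopped increasing (``plateau_len``
    consecutive non-positive one-step differences going backward).  Plateau
    steps only count once the signal has recovered above ``arm_level``;
    this keeps the scan from stopping inside the flat trough of the blink
    itself.
    """
    run = 0
    j = i - 1
    while j >= lo:
        d = v[j] - v[j + 1]
        if d <= 0 and v[j] >= arm_level:
            run += 1
            if run == plateau_len:
                return min(j + plateau_len, i - 1)
        else:
            run = 0
        j -= 1
    return lo


def _scan_forward(
    v: np.ndarray, i: int, hi: int, plateau_len: int, arm_level: float = -np.inf
) -> int:
    """Forward stable-point scan from minimum index ``i`` up to ``hi`` (inclusive)."""
    run = 0
    j = i + 1
    while j <= hi:
        d = v[j] - v[j - 1]
        if d <= 0 and v[j] >= arm_level:
            run += 1
            if run == plateau_len:
                return max(j - plateau_len, i + 1)
        else:
            run = 0
        j += 1
    return hi


def detect_blinks_area(
    s: TimeSeries,
    min_depth_fraction: float = 0.3,
    min_separation_s: float = 0.1,
    *,
    search_window_s: float = 1.0,
    plateau_len: int = 3,
    baseline_window_s: float = 2.0,
) -> list[BlinkEvent]:
    """Detect blinks in a (preferably up-sampled) eye-area signal.

    Procedure:

    1. invalid samples are bridged linearly;
    2. a candidate sample must be the minimum within ±``min_separation_s``/2
       and must dip below the local rolling-median baseline by at least
       ``min_depth_fraction`` of that baseline (noise dips are shallow and
       are rejected here);
    3. candidates closer than ``min_separation_s`` are clustered; the
       deepest sample of a cluster (earliest on ties) is the blink minimum;
    4. from each minimum the signal is scanned backward and forward up to
       ``search_window_s`` for the stable points where it stops increasing;
       a plateau only qualifies once the signal has recovered at least half
       the blink depth (otherwise the flat trough of the blink itself would
       terminate the scan); these become the blink start and end;
    5. overlapping events are merged (their deepest minimum is kept).

    The signal should span at least one second.
    """
    if len(s) < 2:
        raise ValueError("series too short")
    if s.t_end - s.t_start < 1.0:
        raise ValueError("need at least 1 s of signal")
    v = _bridge_invalid(s.values, s.valid)
    t = s.times
    n = len(v)
    rate = s.nominal_rate or (n - 1) / (t[-1] - t[0])

    half_base = max(1, int(round(baseline_window_s * rate / 2)))
    baseline = _rolling_median(v, half_base)

    m = max(1, int(round(min_separation_s * rate / 2)))
    from scipy.ndimage import minimum_filter

    window_min = minimum_filter(v, size=2 * m + 1, mode="nearest")
    depth = baseline - v
    is_cand = (v <= window_min) & (depth > 0) & (depth >= min_depth_fraction * baseline)
    is_cand[0] = is_cand[-1] = False
    cand = np.flatnonzero(is_cand).tolist()
    if not cand:
        return []

    # cluster candidates separated by less than min_separation_s
    clusters: list[list[int]] = [[cand[0]]]
    for i in cand[1:]:
        if t[i] - t[clusters[-1][-1]] <= min_separation_s:
            clusters[-1].append(i)
        else:
            clusters.append([i])

    w = int(round(search_window_s * rate))
    raw: list[tuple[int, int, int]] = []
    for cluster in clusters:
        vals = v[cluster]
        i = cluster[int(np.argmin(vals))]  # earliest on ties (argmin rule)
        if i <= 0 or i >= n - 1:
            continue
        arm = v[i] + 0.5 * (baseline[i] - v[i])
        a = _scan_backward(v, i, max(0, i - w), plateau_len, arm)
        b = _scan_forward(v, i, min(n - 1, i + w), plateau_len, arm)
        raw.append((a, i, b))

    # merge overlapping events, keeping the deepest minimum
    raw.sort()
    merged: list[tuple[int, int, int]] = []
    for a, i, b in raw:
        if merged and a <= merged[-1][2]:
            pa, pi, pb = merged[-1]
            best = pi if v[pi] <= v[i] else i
            merged[-1] = (pa, best, max(pb, b))
        else:
            merged.append((a, i, b))

    return [
        BlinkEvent(float(t[a]), float(t[i]), float(t[b]), source="glass")
        for a, i, b in merged
        if a < i < b
    ]


# ---------------------------------------------------------------------------
# Blink detection — EyeLink-style pupil signal
# ---------------------------------------------------------------------------


def _missing_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of invalid samples as inclusive (first, last) index pairs."""
    runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for i, ok in enumerate(valid):
        if not ok and not in_run:
            in_run, start = True, i
        elif ok and in_run:
            runs.append((start, i - 1))
            in_run = False
    if in_run:
        runs.append((start, len(valid) - 1))
    return runs


def detect_blinks_pupil(
    p: TimeSeries,
    *,
    search_window_s: float = 1.0,
    plateau_len: int = 3,
) -> list[BlinkEvent]:
    """Reconstruct blink extents from a pupil-area signal with missing runs.

    The tracker reports "no pupil" only while the eye is fully closed, so
    each maximal missing-sample run is extended backward and forward to the
    stable points where the pupil size stops increasing; the extended
    interval strictly contains the missing run (except at the recording
    boundary, where it is clamped).  The scans never cross into a
    neighbouring missing run, so closely spaced blinks remain distinct; any
    residual overlap between consecutive events is split at its midpoint.
    """
    if not p.valid.any():
        raise ValueError("pupil series has no valid samples")
    t = p.times
    v = p.values
    n = len(v)
    rate = p.nominal_rate or (n - 1) / (t[-1] - t[0])
    w = int(round(search_window_s * rate))
    runs = _missing_runs(p.valid)

    bounds: list[tuple[float, float, float]] = []
    for a, b in runs:
        lo = max(0, a - w)
        hi = min(n - 1, b + w)
        # do not scan across neighbouring missing runs
        j = a - 1
        while j >= lo and p.valid[j]:
            j -= 1
        lo = j + 1
        j = b + 1
        while j <= hi and p.valid[j]:
            j += 1
        hi = j - 1

        if a - 1 < lo:  # run touches the series start
            si = max(0, a - 1)
        else:
            si = _scan_backward(v, a, lo, plateau_len)
            si = min(si, a - 1)
        if b + 1 > hi:  # run touches the series end
            ei = min(n - 1, b + 1)
        else:
            ei = _scan_forward(v, b, hi, plateau_len)
            ei = max(ei, b + 1)
        if si >= ei:
            continue
        mid = (t[a] + t[b]) / 2.0
        bounds.append((float(t[si]), float(mid), float(t[ei])))

    # split residual overlaps between consecutive events at the midpoint
    events: list[tuple[float, float, float]] = []
    for st, mi, en in bounds:
        if events and st < events[-1][2]:
            cut = (st + events[-1][2]) / 2.0
            pst, pmi, pen = events[-1]
            cut = max(cut, pmi + 1e-9)
            cut = min(cut, mi - 1e-9)
            events[-1] = (pst, pmi, cut)
            st = cut
        events.append((st, mi, en))

    return [
        BlinkEvent(st, mi, en, source="pupil")
        for st, mi, en in events
        if st < mi < en
    ]


def filter_blinks(events: list[BlinkEvent], max_duration_s: float = 2.0) -> list[BlinkEvent]:
    """Drop events strictly longer than ``max_duration_s`` (boundary retained)."""
    return [e for e in events if e.duration <= max_duration_s]
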