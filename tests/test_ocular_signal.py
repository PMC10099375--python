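"""Eye-area/EAR measures, resampling, and both blink detectors."""

import numpy as np
import pytest

from blinkglass import (
    BlinkEvent,
    BlinkWaveformParams,
    EyeShapeParams,
    KeypointSet,
    TimeSeries,
    detect_blinks_area,
    detect_blinks_pupil,
    eye_area_from_keypoints,
    eye_aspect_ratio,
    filter_blinks,
    render_eye_frame,
    synth_blink_recording,
    upsample_series,
)


def hexagon_keypoints(radius=1.0, center=(0.0, 0.0)):
    """Regular hexagon in keypoint order (corners + upper/lower lid pairs)."""
    angles = np.radians([180.0, 120.0, 60.0, 0.0, 300.0, 240.0])
    rows = center[0] - radius * np.sin(angles)
    cols = center[1] + radius * np.cos(angles)
    # polygon vertices P0..P5 -> keypoint slots (corner, corner, up, up, low, low)
    pts = np.zeros((6, 2))
    pts[0] = rows[0], cols[0]
    pts[2] = rows[1], cols[1]
    pts[3] = rows[2], cols[2]
    pts[1] = rows[3], cols[3]
    pts[5] = rows[4], cols[4]
    pts[4] = rows[5], cols[5]
    return pts


class TestEyeArea:
    def test_regular_hexagon_closed_form(self):
        """Circumradius-1 regular hexagon: area = 3*sqrt(3)/2."""
        area = eye_area_from_keypoints(hexagon_keypoints())
        assert area == pytest.approx(3.0 * np.sqrt(3.0) / 2.0, abs=1e-9)

    def test_collinear_points_zero_area(self):
        pts = np.column_stack([np.full(6, 5.0), np.linspace(0, 10, 6)])
        assert eye_area_from_keypoints(pts) == pytest.approx(0.0)

    def test_invalid_keypoint_flags_sample(self):
        ks = KeypointSet(np.zeros((6, 2)), valid=[True] * 5 + [False])
        assert np.isnan(eye_area_from_keypoints(ks))

    def test_matches_rasterization_oracle(self, rng):
        """Shoelace area agrees with pixel counting on random eye-like hexagons."""
        from skimage.draw import polygon as sk_polygon

        from blinkglass.ocular_signal import _HEX_ORDER

        scale = 40.0
        for _ in range(50):
            w = rng.uniform(20, 60)
            cu = np.sort(rng.uniform(5, w - 5, size=2))
            cl = np.sort(rng.uniform(5, w - 5, size=2))
            pts = np.array(
                [
                    [50.0, 10.0],
                    [50.0, 10.0 + w],
                    [50.0 - rng.uniform(3, 15), 10.0 + cu[0]],
                    [50.0 - rng.uniform(3, 15), 10.0 + cu[1]],
                    [50.0 + rng.uniform(3, 15), 10.0 + cl[0]],
                    [50.0 + rng.uniform(3, 15), 10.0 + cl[1]],
                ]
            )
            poly = pts[list(_HEX_ORDER)] * scale
            rr, cc = sk_polygon(poly[:, 0], poly[:, 1])
            raster_area = len(rr) / scale**2
            assert eye_area_from_keypoints(pts) == pytest.approx(raster_area, rel=0.02)


class TestEyeAspectRatio:
    def test_closed_eye_zero(self):
        pts = np.zeros((6, 2))
        pts[1] = (0.0, 10.0)
        pts[2] = pts[4] = (0.0, 3.0)
        pts[3] = pts[5] = (0.0, 7.0)
        assert eye_aspect_ratio(pts) == pytest.approx(0.0)

    def test_half_width_separation(self):
        w = 10.0
        pts = np.array(
            [[0.0, 0.0], [0.0, w], [-2.5, 3.0], [-2.5, 7.0], [2.5, 3.0], [2.5, 7.0]]
        )
        assert eye_aspect_ratio(pts) == pytest.approx(0.5)

    def test_zero_width_rejected(self):
        pts = np.zeros((6, 2))
        with pytest.raises(ValueError):
            eye_aspect_ratio(pts)

    def test_ear_and_area_comonotone_over_openness_sweep(self):
        """Both measures increase together as the renderer opens the eye."""
        areas, ears = [], []
        for openness in np.linspace(0.05, 1.0, 12):
            _, kps = render_eye_frame(EyeShapeParams(openness=float(openness)), seed=0)
            areas.append(eye_area_from_keypoints(kps))
            ears.append(eye_aspect_ratio(kps))
        assert (np.diff(areas) > 0).all()
        assert (np.diff(ears) > 0).all()


class TestUpsampleSeries:
    def test_constant_series(self):
        s = TimeSeries(np.arange(31) / 30.0, np.full(31, 7.0), nominal_rate=30.0)
        up = upsample_series(s, 250.0)
        assert up.nominal_rate == 250.0
        assert np.allclose(up.values, 7.0)
        assert up.times[0] == s.times[0]

    def test_linear_ramp_midpoint(self):
        s = TimeSeries(np.arange(31) / 30.0, np.arange(31) / 30.0, nominal_rate=30.0)
        up = upsample_series(s, 250.0)
        k = np.argmin(np.abs(up.times - 0.5))
        assert up.values[k] == pytest.approx(0.5, abs=1e-6)

    def test_sinusoid_round_trip_error(self):
        """A 2 Hz sinusoid sampled at 30 Hz interpolates to 250 Hz within 2%."""
        t30 = np.arange(0, 61) / 30.0
        s = TimeSeries(t30, 1.0 + 0.5 * np.sin(2 * np.pi * 2.0 * t30), nominal_rate=30.0)
        up = upsample_series(s, 250.0)
        truth = 1.0 + 0.5 * np.sin(2 * np.pi * 2.0 * up.times)
        assert np.abs(up.values - truth).max() < 0.02 * 0.5 * 2  # 2% of amplitude span

    def test_single_sample_rejected(self):
        s = TimeSeries([0.0, 1.0], [1.0, 1.0], [True, False])
        with pytest.raises(ValueError):
            upsample_series(s)


# ---------------------------------------------------------------------------
# Brute-force reference detector (independent naive implementation)
# ---------------------------------------------------------------------------


def oracle_detect_area(
    s,
    min_depth_fraction=0.3,
    min_separation_s=0.1,
    search_window_s=1.0,
    plateau_len=3,
    baseline_window_s=2.0,
):
    """Naive detector: tests every sample as a candidate minimum and scans
    plateaus sample by sample.  Mirrors the documented rules with plain
    Python loops and no shared code paths."""
    t = list(s.times)
    n = len(t)
    # bridge invalid samples
    v = []
    valid_idx = [i for i in range(n) if s.valid[i]]
    for i in range(n):
        if s.valid[i]:
            v.append(float(s.values[i]))
        else:
            prev = max([j for j in valid_idx if j < i], default=None)
            nxt = min([j for j in valid_idx if j > i], default=None)
            if prev is None:
                v.append(float(s.values[nxt]))
            elif nxt is None:
                v.append(float(s.values[prev]))
            else:
                f = (i - prev) / (nxt - prev)
                v.append(float(s.values[prev]) * (1 - f) + float(s.values[nxt]) * f)
    rate = s.nominal_rate or (n - 1) / (t[-1] - t[0])
    half = max(1, round(baseline_window_s * rate / 2))
    # centred median over a replicate-padded window, one sample at a time
    padded = [v[0]] * half + v + [v[-1]] * half
    base = [float(np.median(padded[i : i + 2 * half + 1])) for i in range(n)]
    m = max(1, round(min_separation_s * rate / 2))

    cand = []
    for i in range(1, n - 1):
        wmin = min(v[max(0, i - m) : min(n, i + m + 1)])
        depth = base[i] - v[i]
        if v[i] <= wmin and depth > 0 and depth >= min_depth_fraction * base[i]:
            cand.append(i)
    clusters = []
    for i in cand:
        if clusters and t[i] - t[clusters[-1][-1]] <= min_separation_s:
            clusters[-1].append(i)
        else:
            clusters.append([i])

    w = round(search_window_s * rate)
    raw = []
    for cluster in clusters:
        i = min(cluster, key=lambda k: (v[k], k))
        if i <= 0 or i >= n - 1:
            continue
        # plateaus count only after half-depth recovery (arming)
        arm = v[i] + 0.5 * (base[i] - v[i])
        # backward plateau scan
        lo = max(0, i - w)
        run, si = 0, lo
        j = i - 1
        while j >= lo:
            if v[j] - v[j + 1] <= 0 and v[j] >= arm:
                run += 1
                if run == plateau_len:
                    si = min(j + plateau_len, i - 1)
                    break
            else:
                run = 0
            j -= 1
        # forward plateau scan
        hi = min(n - 1, i + w)
        run, ei = 0, hi
        j = i + 1
        while j <= hi:
            if v[j] - v[j - 1] <= 0 and v[j] >= arm:
                run += 1
                if run == plateau_len:
                    ei = max(j - plateau_len, i + 1)
                    break
            else:
                run = 0
            j += 1
        raw.append((si, i, ei))

    raw.sort()
    merged = []
    for a, i, b in raw:
        if merged and a <= merged[-1][2]:
            pa, pi, pb = merged[-1]
            best = pi if v[pi] <= v[i] else i
            merged[-1] = (pa, best, max(pb, b))
        else:
            merged.append((a, i, b))
    return [(t[a], t[i], t[b]) for a, i, b in merged if a < i < b]


def match_events(detected, truth, tol_s):
    """Greedy pairing of detected to truth events by minimum distance."""
    pairs = []
    used = set()
    for ev in detected:
        best, best_d = None, np.inf
        for k, tr in enumerate(truth):
            if k in used:
                continue
            d = abs(ev.min_s - tr.min_s)
            if d < best_d:
                best, best_d = k, d
        if best is not None and best_d <= tol_s:
            used.add(best)
            pairs.append((ev, truth[best]))
    return pairs


class TestDetectBlinksArea:
    def test_constant_signal_no_events(self):
        t = np.arange(0, 1500) / 250.0
        s = TimeSeries(t, np.full_like(t, 100.0), nominal_rate=250.0)
        assert detect_blinks_area(s) == []

    def test_single_noiseless_blink_boundaries(self, single_blink_recording):
        """Start/end recovered within one 30 Hz sample of the generator truth."""
        up = upsample_series(single_blink_recording.area_series, 250.0)
        events = detect_blinks_area(up)
        assert len(events) == 1
        truth = single_blink_recording.truth_events[0]
        tol = 1.0 / 30.0 + 1e-9
        assert abs(events[0].start_s - truth.start_s) <= tol
        assert abs(events[0].end_s - truth.end_s) <= tol
        assert truth.start_s <= events[0].min_s <= truth.end_s

    def test_noisy_multi_blink_recall_precision(self):
        """20 blinks, 2% noise: recall and precision both >= 0.95."""
        times = tuple(3.0 + 5.7 * k for k in range(20))
        rec = synth_blink_recording(
            BlinkWaveformParams(
                blink_times=times, duration_s=120.0, noise_sd=0.02 * 2500.0, seed=5
            )
        )
        up = upsample_series(rec.area_series, 250.0)
        events = detect_blinks_area(up)
        pairs = match_events(events, rec.truth_events, tol_s=0.5)
        recall = len(pairs) / len(rec.truth_events)
        precision = len(pairs) / len(events) if events else 0.0
        assert recall >= 0.95
        assert precision >= 0.95

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_oracle(self, seed):
        """Detector output identical to the naive every-sample detector."""
        rng = np.random.default_rng(seed)
        n_blinks = int(rng.integers(1, 5))
        times = np.sort(rng.uniform(2.0, 16.0, size=n_blinks))
        times = tuple(
            t for i, t in enumerate(times) if i == 0 or t - times[i - 1] > 0.6
        )
        rec = synth_blink_recording(
            BlinkWaveformParams(
                blink_times=times,
                duration_s=20.0,
                noise_sd=float(rng.uniform(0, 0.03)) * 2500.0,
                seed=int(rng.integers(1 << 30)),
            )
        )
        up = upsample_series(rec.area_series, 250.0)
        ours = detect_blinks_area(up)
        ref = oracle_detect_area(up)
        assert len(ours) == len(ref)
        for ev, (a, mi, b) in zip(ours, ref):
            assert ev.start_s == pytest.approx(a, abs=1e-12)
            assert ev.min_s == pytest.approx(mi, abs=1e-12)
            assert ev.end_s == pytest.approx(b, abs=1e-12)

    def test_events_sorted_nonoverlapping_within_range(self):
        times = tuple(2.0 + 1.1 * k for k in range(10))
        rec = synth_blink_recording(
            BlinkWaveformParams(blink_times=times, duration_s=15.0, noise_sd=30.0, seed=2)
        )
        up = upsample_series(rec.area_series, 250.0)
        events = detect_blinks_area(up)
        for e in events:
            assert up.t_start <= e.start_s < e.end_s <= up.t_end
        for e1, e2 in zip(events, events[1:]):
            assert e1.end_s <= e2.start_s


class TestDetectBlinksPupil:
    def test_fully_valid_series_no_events(self):
        t = np.arange(0, 2500) / 500.0
        s = TimeSeries(t, np.full_like(t, 900.0), nominal_rate=500.0)
        assert detect_blinks_pupil(s) == []

    def test_noiseless_blink_extension(self, single_blink_recording):
        """Extended interval strictly contains the missing run and matches the
        truth excursion within one 500 Hz sample."""
        p = single_blink_recording.pupil_series
        events = detect_blinks_pupil(p)
        assert len(events) == 1
        ev = events[0]
        truth = single_blink_recording.truth_events[0]
        run_t = p.times[~p.valid]
        assert ev.start_s < run_t[0]
        assert ev.end_s > run_t[-1]
        assert ev.duration > run_t[-1] - run_t[0]
        tol = 1.0 / 500.0 + 1e-9
        assert abs(ev.start_s - truth.start_s) <= tol
        assert abs(ev.end_s - truth.end_s) <= tol

    def test_two_runs_with_brief_rebound_stay_distinct(self):
        """Two missing runs separated by 50 ms of valid rebound: two events."""
        rate = 500.0
        t = np.arange(0, int(2.0 * rate)) / rate
        v = np.full_like(t, 1000.0)
        valid = np.ones_like(t, dtype=bool)
        # two blinks with a partial rebound between their missing runs
        def dip(center, half):
            seg = np.abs(t - center) < half
            v[seg] = 1000.0 * np.clip((np.abs(t[seg] - center) / half), 0.05, None)
        dip(0.9, 0.1)
        dip(1.05, 0.1)
        valid[(t > 0.85) & (t < 0.95)] = False
        valid[(t > 1.0) & (t < 1.1)] = False
        v[~valid] = 0.0
        s = TimeSeries(t, v, valid, nominal_rate=rate)
        events = detect_blinks_pupil(s)
        assert len(events) == 2
        assert events[0].end_s <= events[1].start_s

    def test_all_invalid_rejected(self):
        t = np.arange(0, 100) / 500.0
        s = TimeSeries(t, np.zeros_like(t), np.zeros(len(t), dtype=bool), nominal_rate=500.0)
        with pytest.raises(ValueError):
            detect_blinks_pupil(s)

    def test_glass_events_longer_than_pupil_missing_runs(self):
        """The area-signal blink spans the whole eyelid excursion, the pupil
        missing run only full closure, so glass events are longer."""
        times = (3.0, 6.0, 9.0)
        rec = synth_blink_recording(
            BlinkWaveformParams(blink_times=times, duration_s=12.0, noise_sd=0.0)
        )
        glass = detect_blinks_area(upsample_series(rec.area_series, 250.0))
        pupil = detect_blinks_pupil(rec.pupil_series)
        assert len(glass) == len(pupil) == 3
        p = rec.pupil_series
        runs = []
        in_run = False
        for i, ok in enumerate(p.valid):
            if not ok and not in_run:
                in_run, start = True, p.times[i]
            elif ok and in_run:
                runs.append((start, p.times[i - 1]))
                in_run = False
        for g, (rs, re) in zip(glass, runs):
            assert g.duration >= re - rs


class TestFilterBlinks:
    def _ev(self, start, dur):
        return BlinkEvent(start, start + dur / 2, start + dur)

    def test_strictly_longer_removed(self):
        events = [self._ev(0.0, 0.3), self._ev(1.0, 2.5), self._ev(4.0, 0.4)]
        kept = filter_blinks(events, 2.0)
        assert [e.duration for e in kept] == pytest.approx([0.3, 0.4])

    def test_boundary_duration_retained(self):
        """Exactly 2.0 s is kept: the exclusion rule is strict."""
        events = [self._ev(0.0, 2.0)]
        assert filter_blinks(events, 2.0) == events

    def test_empty_list(self):
        assert filter_blinks([], 2.0) == []
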