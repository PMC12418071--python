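"""Gaze-event classification for head-free VR eye tracking.

Free exploration in a virtual environment superimposes observer motion on
the recorded gaze-in-world signal: while the eye stabilizes a world point,
translation of the head produces a compensatory rotation of the gaze
direction that a naive velocity criterion mistakes for eye movement. This
module (a) removes that translational component, (b) computes angular
velocity on the sphere, (c) derives data-driven velocity thresholds per
time interval, and (d) segments the recording into an alternating sequence
of saccades and fixations.

Angles are degrees throughout; gaze directions are (azimuth, elevation)
pairs in the world frame with the unit-vector convention
``v = (cos el sin az, sin el, cos el cos az)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

SACCADE = "saccade"
FIXATION = "fixation"
GAP = "gap"


# ---------------------------------------------------------------------------
# direction helpers

def angles_to_vec(az_deg, el_deg):
    """(azimuth, elevation) in degrees -> unit vectors, shape (..., 3)."""
    az = np.deg2rad(np.asarray(az_deg, dtype=float))
    el = np.deg2rad(np.asarray(el_deg, dtype=float))
    return np.stack(
        [np.cos(el) * np.sin(az), np.sin(el), np.cos(el) * np.cos(az)], axis=-1
    )


def vec_to_angles(v):
    """Unit vectors -> (azimuth, elevation) in degrees."""
    v = np.asarray(v, dtype=float)
    az = np.degrees(np.arctan2(v[..., 0], v[..., 2]))
    el = np.degrees(np.arcsin(np.clip(v[..., 1], -1.0, 1.0)))
    return az, el


def great_circle_deg(u, v):
    """Great-circle angle between unit vectors, degrees.

    Uses atan2(|u x v|, u . v): exact zero for identical vectors and
    well-conditioned for the sub-arcminute angles of fixational jitter.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    cross = np.linalg.norm(np.cross(u, v), axis=-1)
    dot = np.sum(u * v, axis=-1)
    return np.degrees(np.arctan2(cross, dot))


# ---------------------------------------------------------------------------
# containers

@dataclass
class GazeTrace:
    """Timestamped gaze + head samples from one session.

    time
        seconds, strictly increasing.
    az, el
        gaze direction in the world frame, degrees.
    head_pos
        (n, 3) head position in meters; may be ``None`` for head-fixed data.
    head_yaw
        head orientation about the vertical axis, degrees.
    gaze_dist
        distance from the head to the fixated world point, meters;
        required by :func:`correct_translation`.
    rate
        nominal sampling rate, Hz.
    """

    time: np.ndarray
    az: np.ndarray
    el: np.ndarray
    rate: float
    head_pos: np.ndarray | None = None
    head_yaw: np.ndarray | None = None
    gaze_dist: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        self.el = np.asarray(self.el, dtype=float)
        if self.time.ndim != 1 or len(self.time) != len(self.az) != len(self.el):
            raise ValueError("time, az, el must be 1-D arrays of equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("gaze timestamps must be strictly increasing")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self):
        return len(self.time)

    @property
    def directions(self) -> np.ndarray:
        return angles_to_vec(self.az, self.el)


@dataclass
class VelocitySeries:
    """Angular gaze velocity, degrees/second, on the interior samples."""

    time: np.ndarray
    omega: np.ndarray
    corrected: bool = False

    def __len__(self):
        return len(self.time)


@dataclass
class GazeEvent:
    kind: str  # saccade | fixation | gap
    onset: float
    offset: float
    category: str = "none"
    amplitude: float | None = None

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("event offset must exceed onset")


@dataclass
class ThresholdSchedule:
    """Per-interval velocity thresholds tiling [edges[0], edges[-1]]."""

    edges: np.ndarray  # len n_intervals + 1
    thresholds: np.ndarray  # len n_intervals
    lam: float = 5.0

    def at(self, times) -> np.ndarray:
        """Threshold applying at each time (deg/s)."""
        idx = np.clip(
            np.searchsorted(self.edges, times, side="right") - 1,
            0,
            len(self.thresholds) - 1,
        )
        return self.thresholds[idx]


# ---------------------------------------------------------------------------
# operations

def correct_translation(trace: GazeTrace, ref: str = "median") -> GazeTrace:
    """Remove observer-translation contamination from the gaze signal.

    The recorded gaze direction points from the *moving* head to the
    fixated world point; translation therefore rotates it even when the
    gaze point is perfectly stable. Using the per-sample gaze distance the
    fixated world point is reconstructed and re-expressed from a fixed
    vantage (the median head position), so that a stable gaze point maps
    to a constant direction regardless of head translation.

    A static-head trace is returned unchanged (up to floating-point
    round-off in the re-projection).
    """
    if trace.head_pos is None:
        raise ValueError("correct_translation requires the 'head_pos' channel")
    if trace.gaze_dist is None:
        raise ValueError("correct_translation requires the 'gaze_dist' channel")
    h = np.asarray(trace.head_pos, dtype=float)
    d = np.asarray(trace.gaze_dist, dtype=float)[:, None]
    g = trace.directions
    target = h + d * g
    if ref != "median":
        raise ValueError(f"unknown reference policy {ref!r}")
    h_ref = np.median(h, axis=0)
    rel = target - h_ref
    dist = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore"):
        rel = rel / dist[:, None]
    az, el = vec_to_angles(rel)
    return replace(trace, az=az, el=el, gaze_dist=dist)


def angular_velocity(trace: GazeTrace, smooth: int = 1) -> VelocitySeries:
    """Central-difference angular speed of the gaze direction.

    omega[i] is the great-circle angle between the directions at i-1 and
    i+1 divided by t[i+1] - t[i-1]; endpoints are dropped. ``smooth`` > 1
    applies a moving average (edge-shortened) to the direction components
    before differencing — it suppresses single-sample tracker noise at
    the cost of smearing onsets by roughly an extra sample, so the
    default differencing stencil is left unsmoothed. NaN samples
    propagate to every estimate whose stencil touches them.
    """
    if len(trace) < 3:
        raise ValueError("need at least 3 samples for a velocity estimate")
    v = trace.directions
    if smooth > 1:
        kernel = np.ones(smooth)
        counts = np.convolve(np.ones(len(v)), kernel, mode="same")
        sm = np.empty_like(v)
        for k in range(3):
            sm[:, k] = np.convolve(v[:, k], kernel, mode="same") / counts
        norm = np.linalg.norm(sm, axis=1)
        with np.errstate(invalid="ignore"):
            v = sm / norm[:, None]
    dt = trace.time[2:] - trace.time[:-2]
    ang = great_circle_deg(v[:-2], v[2:])
    omega = ang / dt
    return VelocitySeries(time=trace.time[1:-1].copy(), omega=omega)


def _robust_sd(x: np.ndarray) -> float:
    """MAD-based robust scale: 1.4826 * median(|x - median(x)|).

    Median-of-squares scale estimators from the microsaccade-threshold
    literature apply to *signed* velocity components; on a nonnegative
    speed series they degenerate (squaring is monotone, so the median of
    the squares is essentially the square of the median). The MAD keeps
    the robustness-to-saccade-samples property without that degeneracy.
    """
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def adaptive_thresholds(
    vel: VelocitySeries, interval_len: float = 10.0, lam: float = 5.0
) -> ThresholdSchedule:
    """Data-driven saccade threshold per time interval.

    The series is tiled into ``interval_len``-second intervals (the final
    partial interval is merged into its predecessor) and each interval
    gets threshold = median(omega) + lam * robust-SD(omega). Intervals
    containing only NaNs inherit the previous interval's threshold.
    """
    if interval_len < 1.0:
        raise ValueError("interval_len must be at least 1 s")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    t0, t1 = vel.time[0], vel.time[-1]
    n_int = max(1, int(np.floor((t1 - t0) / interval_len)))
    edges = t0 + np.arange(n_int + 1) * interval_len
    edges[-1] = np.nextafter(t1, np.inf)  # merge trailing partial interval
    thresholds = np.empty(n_int)
    prev = np.nan
    for i in range(n_int):
        sel = (vel.time >= edges[i]) & (vel.time < edges[i + 1])
        x = vel.omega[sel]
        x = x[np.isfinite(x)]
        if len(x) == 0:
            logger.warning(
                "interval %d [%0.1f, %0.1f) s has no finite velocities; "
                "inheriting previous threshold",
                i, edges[i], edges[i + 1],
            )
            thresholds[i] = prev
        else:
            thresholds[i] = np.median(x) + lam * _robust_sd(x)
        prev = thresholds[i]
    if np.isnan(thresholds[0]):
        # leading all-NaN intervals inherit the first defined threshold
        defined = np.flatnonzero(np.isfinite(thresholds))
        if len(defined) == 0:
            raise ValueError("no interval contains finite velocities")
        thresholds[: defined[0]] = thresholds[defined[0]]
    return ThresholdSchedule(edges=edges, thresholds=thresholds, lam=lam)


def _runs(labels: np.ndarray):
    """Yield (start, stop, value) for maximal constant runs (stop exclusive)."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(labels)]])
    return [(int(a), int(b), int(labels[a])) for a, b in zip(starts, stops)]


def _segment_events(
    time: np.ndarray,
    supra: np.ndarray,
    min_sacc: float,
    min_fix: float,
    omega: np.ndarray | None = None,
    thr: np.ndarray | None = None,
) -> list[GazeEvent]:
    """Classify one gap-free segment into alternating saccades/fixations."""
    labels = supra.astype(np.int8)
    # Iteratively absorb sub-minimum runs. Supra runs shorter than min_sacc
    # are always demoted to fixation; interior sub-minimum fixation runs
    # (flanked by saccades) are promoted, merging the saccades.
    for _ in range(10):
        changed = False
        runs = _runs(labels)
        for k, (a, b, val) in enumerate(runs):
            # run duration measured to the start of the next run (or series end)
            dur = (time[b] if b < len(time) else time[-1]) - time[a]
            if val == 1 and dur < min_sacc:
                labels[a:b] = 0
                changed = True
            elif (
                val == 0
                and dur < min_fix
                and 0 < k < len(runs) - 1
                and runs[k - 1][2] == 1
                and runs[k + 1][2] == 1
            ):
                labels[a:b] = 1
                changed = True
        if not changed:
            break
    runs = _runs(labels)

    def boundary(a: int) -> float:
        """Sub-sample boundary time at run start index ``a``.

        The threshold crossing between samples a-1 and a, linearly
        interpolated on the velocity trace; falls back to the sample time
        when the velocities do not bracket the threshold (NaNs, merges).
        """
        if omega is None or thr is None or a == 0:
            return float(time[a])
        lo, hi = omega[a - 1], omega[a]
        level = thr[a]
        if np.isfinite(lo) and np.isfinite(hi) and (lo - level) * (hi - level) < 0:
            frac = (level - lo) / (hi - lo)
            return float(time[a - 1] + frac * (time[a] - time[a - 1]))
        return float(time[a])

    events = []
    for k, (a, b, val) in enumerate(runs):
        onset = boundary(a)
        offset = boundary(b) if b < len(time) else float(time[-1])
        if offset <= onset:
            continue  # zero-length trailing run
        events.append(GazeEvent(kind=SACCADE if val else FIXATION, onset=onset, offset=offset))
    return events


def classify_events(
    vel: VelocitySeries,
    sched: ThresholdSchedule,
    min_sacc: float = 0.022,
    min_fix: float = 0.050,
    max_gap: float = 0.100,
    interp_boundaries: bool = True,
) -> list[GazeEvent]:
    """Threshold the velocity series into saccades and fixations.

    Maximal supra-threshold runs lasting at least ``min_sacc`` become
    saccades; the complement becomes fixations (runs shorter than
    ``min_fix`` between two saccades are merged into one saccade).
    With ``interp_boundaries`` (default) event boundaries are placed at
    the sub-sample threshold crossing, linearly interpolated on the
    velocity trace, instead of on the sample grid. Tracker
    dropouts — NaN runs or sampling holes longer than ``max_gap`` —
    become explicit gap events and are never bridged. Within each
    gap-free segment the output alternates strictly; the union of events
    and gaps tiles the series span exactly.
    """
    n = len(vel)
    if n == 0:
        return []
    thr = sched.at(vel.time)
    finite = np.isfinite(vel.omega)
    # segment boundaries: long NaN runs or long sampling holes
    bad = ~finite
    events: list[GazeEvent] = []
    # Identify "gap" sample spans: NaN runs whose temporal extent > max_gap.
    seg_break = np.zeros(n, dtype=bool)  # True = sample belongs to a gap
    for a, b, val in _runs(bad.astype(np.int8)):
        if val == 1:
            extent = vel.time[min(b, n - 1)] - vel.time[a]
            if extent > max_gap:
                seg_break[a:b] = True
    # sampling holes
    hole_after = np.diff(vel.time) > max_gap

    # build segments of consecutive usable samples
    seg_start = 0
    cursor = 0
    segments = []  # (start, stop) inclusive-exclusive index ranges, usable
    i = 0
    while i < n:
        if seg_break[i]:
            j = i
            while j < n and seg_break[j]:
                j += 1
            if i > seg_start:
                segments.append((seg_start, i))
            events.append(
                GazeEvent(kind=GAP, onset=vel.time[i], offset=vel.time[min(j, n - 1)])
            )
            seg_start = j
            i = j
        else:
            if i + 1 < n and hole_after[i]:
                segments.append((seg_start, i + 1))
                events.append(GazeEvent(kind=GAP, onset=vel.time[i], offset=vel.time[i + 1]))
                seg_start = i + 1
            i += 1
    if seg_start < n:
        segments.append((seg_start, n))

    for a, b in segments:
        t = vel.time[a:b]
        if len(t) < 2:
            continue
        om = vel.omega[a:b]
        th = thr[a:b]
        supra = np.where(np.isfinite(om), om > th, False)
        events.extend(
            _segment_events(
                t, supra, min_sacc, min_fix,
                omega=om if interp_boundaries else None,
                thr=th if interp_boundaries else None,
            )
        )
    events.sort(key=lambda e: e.onset)
    return events


def saccade_amplitude(trace: GazeTrace, ev: GazeEvent) -> float:
    """Great-circle angle (degrees) between gaze at event onset and offset."""
    if ev.kind != SACCADE:
        raise ValueError("amplitude is defined for saccades only")
    if ev.onset < trace.time[0] - 1e-9 or ev.offset > trace.time[-1] + 1e-9:
        raise ValueError("event lies outside the gaze trace")
    i = int(np.clip(np.searchsorted(trace.time, ev.onset - 1e-12), 0, len(trace) - 1))
    j = int(np.clip(np.searchsorted(trace.time, ev.offset - 1e-12), 0, len(trace) - 1))
    v = trace.directions
    return float(great_circle_deg(v[i], v[j]))


def annotate_amplitudes(trace: GazeTrace, events: list[GazeEvent]) -> list[GazeEvent]:
    """Fill the amplitude field of every saccade event (in place); returns events."""
    for ev in events:
        if ev.kind == SACCADE:
            ev.amplitude = saccade_amplitude(trace, ev)
    return events


def detect_gaze_events(
    trace: GazeTrace,
    interval_len: float = 10.0,
    lam: float = 5.0,
    min_sacc: float = 0.022,
    min_fix: float = 0.050,
    correct: bool = True,
    smooth: int = 1,
) -> list[GazeEvent]:
    """End-to-end detection: correction -> velocity -> thresholds -> events.

    ``correct`` applies :func:`correct_translation` first when head data
    are present; it is a no-op for head-fixed traces.
    """
    work = trace
    if correct and trace.head_pos is not None and trace.gaze_dist is not None:
        work = correct_translation(trace)
    vel = angular_velocity(work, smooth=smooth)
    sched = adaptive_thresholds(vel, interval_len=interval_len, lam=lam)
    events = classify_events(vel, sched, min_sacc=min_sacc, min_fix=min_fix)
    return annotate_amplitudes(work, events)
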