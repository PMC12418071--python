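"""Descriptive statistics of gaze events.

Robust per-category location/spread summaries (median and MAD), temporal
cumulative distributions of fixations, the across-trial variability of
angular velocity around event onsets (a bias check on the event
classifier), and hierarchical circular statistics of viewing angles.

SD convention: sample SD (ddof=1) throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .gaze import FIXATION, SACCADE, GazeEvent, VelocitySeries

logger = logging.getLogger(__name__)


def events_to_frame(events: list[GazeEvent]) -> pd.DataFrame:
    rows = [
        (e.onset, e.offset, e.kind, e.category, e.duration, e.amplitude)
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=["onset_s", "offset_s", "kind", "category", "duration_s", "amplitude_deg"],
    )


def mad(x) -> float:
    """Median absolute deviation: median(|x - median(x)|)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def summarize_categories(events) -> pd.DataFrame:
    """Median and MAD of event measures per stimulus category.

    Accepts a list of :class:`GazeEvent` or an event DataFrame. Returns a
    tidy frame indexed by (category, measure) with columns n / median /
    mad; empty category-measure cells get n=0 and NaN statistics.
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    categories = ("background", "body", "head")
    measures = {
        "fixation_duration_s": (FIXATION, "duration_s"),
        "saccade_duration_s": (SACCADE, "duration_s"),
        "saccade_amplitude_deg": (SACCADE, "amplitude_deg"),
    }
    rows = []
    for cat in categories:
        for name, (kind, col) in measures.items():
            x = df.loc[(df["kind"] == kind) & (df["category"] == cat), col].dropna()
            if len(x) == 0:
                rows.append((cat, name, 0, np.nan, np.nan))
            else:
                rows.append((cat, name, len(x), float(x.median()), mad(x)))
    return pd.DataFrame(
        rows, columns=["category", "measure", "n", "median", "mad"]
    ).set_index(["category", "measure"])


def fixation_cdf(events, session_span: float) -> dict:
    """Cumulative fraction of fixation onsets over time, per category.

    Returns {category: (times, cumulative fraction)}; a nonempty category
    is nondecreasing and ends at 1; empty categories map to None
    (undefined-flagged).
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    fix = df[df["kind"] == FIXATION]
    out = {}
    for cat, grp in fix.groupby("category"):
        onsets = np.sort(grp["onset_s"].to_numpy(dtype=float))
        if len(onsets) == 0:
            out[cat] = None
            continue
        if onsets[-1] > session_span + 1e-9:
            raise ValueError("fixation onsets exceed the session span")
        frac = np.arange(1, len(onsets) + 1) / len(onsets)
        out[cat] = (onsets, frac)
    return out


def onset_velocity_variability(
    vel: VelocitySeries,
    events,
    alignment: str = SACCADE,
    half_window: int = 10,
):
    """Across-trial SD of angular velocity at each lag around event onsets.

    For each lag in [-half_window, +half_window] samples, the sample SD
    across trials of omega at onset+lag. Events whose window leaves the
    series are dropped (logged). Returns (lags, sd, n_trials).
    """
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    onsets = df.loc[df["kind"] == alignment, "onset_s"].to_numpy(dtype=float)
    if len(onsets) < 2:
        raise ValueError("need at least 2 events")
    centers = np.searchsorted(vel.time, onsets - 1e-12)
    ok = (centers - half_window >= 0) & (centers + half_window < len(vel.time))
    n_drop = int(np.sum(~ok))
    if n_drop:
        logger.info("dropping %d events too close to the trace edges", n_drop)
    centers = centers[ok]
    if len(centers) < 2:
        raise ValueError("fewer than 2 events fit the requested window")
    lags = np.arange(-half_window, half_window + 1)
    mat = vel.omega[centers[:, None] + lags[None, :]]
    sd = np.nanstd(mat, axis=0, ddof=1)
    return lags, sd, len(centers)


def circular_stats(angles_deg, subjects):
    """Hierarchical circular mean and SD of viewing angles.

    Within-subject circular means via the resultant vector, then the
    circular mean and circular SD (sqrt(-2 ln R), in degrees) across the
    subject means. Angles in [-180, 180); 0 deg = facing the pedestrian's
    face, +-180 deg = back of the head, clockwise positive. Returns
    (mean_deg, sd_deg); a vanishing resultant yields (nan, nan).
    """
    angles = np.asarray(angles_deg, dtype=float)
    subjects = np.asarray(subjects)
    if np.any((angles < -180.0) | (angles >= 180.0 + 1e-9)):
        raise ValueError("angles must lie in [-180, 180)")
    means = []
    for s in np.unique(subjects):
        a = np.deg2rad(angles[subjects == s])
        means.append(stats.circmean(a, high=np.pi, low=-np.pi))
    means = np.asarray(means)
    vec = np.exp(1j * means)
    r = np.abs(vec.mean())
    if r < 1e-12:
        logger.warning("vanishing resultant vector; circular mean undefined")
        return float("nan"), float("nan")
    grand = np.degrees(np.angle(vec.mean()))
    sd = np.degrees(np.sqrt(-2.0 * np.log(r)))
    return float(grand), float(sd)


def count_correlation(counts_a, counts_b):
    """Pearson correlation of per-subject trial counts between two categories.

    Mirrors the check that looking at bodies and looking at heads are
    independent tendencies across subjects; returns (r, p).
    """
    r, p = stats.pearsonr(np.asarray(counts_a, float), np.asarray(counts_b, float))
    return float(r), float(p)
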