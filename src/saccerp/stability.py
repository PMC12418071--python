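"""Temporal stability of the P100 under fixation- vs saccade-onset alignment.

When the P100 is locked to the saccade onset, fixation-aligned trials
smear it: the component's latency relative to the fixation onset varies
with each trial's preceding-saccade duration. Binning trials by saccade
duration and measuring the half-maximum point of the P100 rising slope
per bin turns this into a statistic: the across-bin standard deviation of
half-maximum latencies is large for fixation alignment and near the noise
floor for saccade alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .epochs import EpochSet, average_erp

logger = logging.getLogger(__name__)

#: default P100 search windows (s), per alignment
SEARCH_WINDOWS = {"saccade": (0.06, 0.25), "fixation": (0.03, 0.2)}
BASELINE_WINDOW = (-0.2, -0.05)


@dataclass
class BinnedErp:
    index: int
    duration_range: tuple[float, float]  # seconds
    erp: np.ndarray  # channels x time (within-subject then across-subject mean)
    times: np.ndarray
    n_trials: int
    labels: tuple = ()


@dataclass
class StabilityResult:
    latencies_fix: np.ndarray  # ms, per bin
    latencies_sacc: np.ndarray
    sd_fix: float  # ms
    sd_sacc: float
    t: float
    df: int
    p: float


def duration_bins(durations: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Partition trials into equal-count bins (+-1) by saccade duration.

    Ties straddling a boundary are broken by stable trial order. The same
    partition must be reused for both alignments, so bins are defined
    once on the durations.
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    durations = np.asarray(durations, dtype=float)
    if len(durations) < n_bins:
        raise ValueError("fewer trials than bins")
    order = np.argsort(durations, kind="stable")
    return [np.sort(part) for part in np.array_split(order, n_bins)]


def bin_by_duration(
    epochs: EpochSet, n_bins: int = 10, bins: list[np.ndarray] | None = None
) -> list[BinnedErp]:
    """Equal-count duration bins, each averaged within then across subjects."""
    md = epochs.metadata
    if "saccade_duration" not in md.columns:
        raise ValueError("trials carry no saccade_duration metadata")
    durations = md["saccade_duration"].to_numpy(dtype=float)
    if bins is None:
        bins = duration_bins(durations, n_bins)
    out = []
    for b, idx in enumerate(bins):
        sub = EpochSet(
            epochs.data[idx],
            epochs.times,
            epochs.alignment,
            md.iloc[idx].assign(_all="all"),
            epochs.labels,
        )
        erp = average_erp(sub, by="_all")["all"]
        d = durations[idx]
        out.append(
            BinnedErp(
                index=b,
                duration_range=(float(d.min()), float(d.max())),
                erp=erp.mean,
                times=epochs.times,
                n_trials=len(idx),
                labels=epochs.labels,
            )
        )
    return out


def half_max_latency(
    trace: np.ndarray,
    times: np.ndarray,
    search_window: tuple[float, float],
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    ref: str = "baseline",
) -> float:
    """Half-maximum point of the P100 rising slope, in ms.

    The peak is the maximum inside ``search_window``; the reference level
    is the mean over ``baseline_window`` (or zero with ``ref="zero"``);
    the latency is the first upward crossing of reference + (peak -
    reference)/2 before the peak, linearly interpolated between samples.
    Returns NaN when the trace never crosses the level (flagged
    undefined); peaks on the window edge are accepted with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    sel = np.flatnonzero((times >= search_window[0]) & (times <= search_window[1]))
    if len(sel) < 2:
        raise ValueError("search window contains fewer than 2 samples")
    seg = trace[sel]
    k = int(np.argmax(seg))
    peak_idx = sel[k]
    if k in (0, len(seg) - 1):
        logger.warning("P100 peak lies on the search-window edge")
    if ref == "zero":
        reference = 0.0
    elif ref == "baseline":
        bsel = (times >= baseline_window[0]) & (times <= baseline_window[1])
        if not np.any(bsel):
            raise ValueError("baseline window lies outside the epoch")
        reference = float(trace[bsel].mean())
    else:
        raise ValueError(f"unknown reference policy {ref!r}")
    level = reference + 0.5 * (trace[peak_idx] - reference)
    # first upward crossing of `level` before the peak, inside the window
    for i in range(sel[0] + 1, peak_idx + 1):
        if trace[i - 1] < level <= trace[i]:
            lo, hi = trace[i - 1], trace[i]
            frac = (level - lo) / (hi - lo) if hi != lo else 0.0
            t_cross = times[i - 1] + frac * (times[i] - times[i - 1])
            return float(t_cross * 1000.0)
    return float("nan")  # no crossing (monotone or already supra-level) -> undefined


def stability_sd(latencies) -> float:
    """Sample SD (ms) of per-bin half-maximum latencies; NaN bins excluded."""
    lat = np.asarray(latencies, dtype=float)
    ok = np.isfinite(lat)
    n_bad = int(np.sum(~ok))
    if n_bad:
        logger.info("excluding %d undefined bins from the stability SD", n_bad)
    if np.sum(ok) < 2:
        raise ValueError("need at least 2 defined latencies")
    return float(np.std(lat[ok], ddof=1))


def paired_bin_test(lat_fix, lat_sacc, method: str = "deviation"):
    """Paired t test of per-bin latency dispersion between alignments.

    ``method="deviation"`` (default) pairs each bin's absolute deviation
    from its alignment's mean latency; ``method="raw"`` pairs the raw
    latencies. Returns (t, df, p); zero variance of the paired
    differences yields an infinite t (flagged).
    """
    a = np.asarray(lat_fix, dtype=float)
    b = np.asarray(lat_sacc, dtype=float)
    if a.shape != b.shape:
        raise ValueError("alignments must have equal bin counts")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise ValueError("need at least 2 paired bins")
    if method == "deviation":
        a = np.abs(a - a.mean())
        b = np.abs(b - b.mean())
    elif method != "raw":
        raise ValueError(f"unknown pairing method {method!r}")
    d = a - b
    df = len(d) - 1
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else float(np.inf) * np.sign(d.mean())
        logger.warning("zero variance of paired differences; t flagged infinite")
        return t, df, 0.0 if np.isinf(t) else 1.0
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def stability_analysis(
    epochs_fix: EpochSet,
    epochs_sacc: EpochSet,
    channel: str = "PO7",
    n_bins: int = 10,
    search_windows: dict | None = None,
    ref: str = "baseline",
) -> StabilityResult:
    """Full stability statistic on a pair of aligned epoch sets.

    The two epoch sets must describe the same trials (the duration-based
    partition is defined once and applied to both).
    """
    windows = dict(SEARCH_WINDOWS)
    if search_windows:
        windows.update(search_windows)
    durations = epochs_fix.metadata["saccade_duration"].to_numpy(dtype=float)
    bins = duration_bins(durations, n_bins)
    ch = list(epochs_fix.labels).index(channel) if epochs_fix.labels else int(channel)

    def latencies(ep: EpochSet, alignment: str) -> np.ndarray:
        binned = bin_by_duration(ep, n_bins, bins=bins)
        return np.array(
            [
                half_max_latency(b.erp[ch], b.times, windows[alignment], ref=ref)
                for b in binned
            ]
        )

    lat_fix = latencies(epochs_fix, "fixation")
    lat_sacc = latencies(epochs_sacc, "saccade")
    t, df, p = paired_bin_test(lat_fix, lat_sacc)
    return StabilityResult(
        latencies_fix=lat_fix,
        latencies_sacc=lat_sacc,
        sd_fix=stability_sd(lat_fix),
        sd_sacc=stability_sd(lat_sacc),
        t=t,
        df=df,
        p=p,
    )
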