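"""Epoch extraction and averaging around gaze-event triggers.

In a free-viewing design there are no stimulus onsets; the "trial" is the
EEG surrounding a detected gaze event. The same underlying data can be
aligned to fixation onsets or to the onset of the saccade that precedes
each fixation — identical trials differing only by a per-trial time shift
equal to the saccade duration. Averaging is two-stage (within subject,
then unweighted across subjects) so that subjects with many trials do not
dominate categories with few (the head category in particular).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .gaze import FIXATION, GAP, SACCADE, GazeEvent

logger = logging.getLogger(__name__)

CATEGORIES = ("background", "body", "head")

#: named epoch windows (seconds relative to the alignment event)
WINDOW_RAW = (-0.3, 0.5)
WINDOW_DECONV = (-0.5, 1.0)


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples in microvolts."""

    data: np.ndarray
    rate: float
    labels: tuple
    t0: float = 0.0
    bad_mask: np.ndarray | None = None  # per-sample True = noisy segment

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("channel label count must match data rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.bad_mask is None:
            self.bad_mask = np.zeros(self.data.shape[1], dtype=bool)
        else:
            self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
            if len(self.bad_mask) != self.data.shape[1]:
                raise ValueError("bad_mask length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate


@dataclass
class EpochSet:
    """trials x channels x time, with a shared time axis and trial metadata."""

    data: np.ndarray
    times: np.ndarray  # seconds relative to the alignment event
    alignment: str  # "fixation" | "saccade"
    metadata: pd.DataFrame  # one row per trial
    labels: tuple = ()

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        if len(self.times) != self.data.shape[2]:
            raise ValueError("time axis length mismatch")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class Erp:
    """Across-subject mean ERP (channels x time)."""

    mean: np.ndarray
    times: np.ndarray
    n_subjects: int
    sem: np.ndarray | None = None
    labels: tuple = ()


def assign_saccade_category(events: list[GazeEvent]) -> list[GazeEvent]:
    """Give each saccade the category of the fixation that follows it.

    The event list must alternate saccade/fixation (gaps allowed as
    separators; alternation is enforced within gap-free stretches). A
    saccade with no succeeding fixation keeps category ``"none"`` and is
    excluded downstream.
    """
    prev_kind = None
    for ev in events:
        if ev.kind == GAP:
            prev_kind = None
            continue
        if prev_kind is not None and ev.kind == prev_kind:
            raise ValueError("event list does not alternate saccade/fixation")
        prev_kind = ev.kind
    for i, ev in enumerate(events):
        if ev.kind != SACCADE:
            continue
        if i + 1 < len(events) and events[i + 1].kind == FIXATION:
            ev.category = events[i + 1].category
        else:
            ev.category = "none"
    return events


def extract_epochs(
    eeg: EEGRecording,
    trigger_samples: np.ndarray,
    window: tuple[float, float],
    metadata: pd.DataFrame | None = None,
    alignment: str = "saccade",
    bad_fraction: float = 0.0,
    baseline: tuple[float, float] | None = None,
) -> EpochSet:
    """Slice one epoch per trigger on a shared time axis.

    Trials whose window leaves the recording are dropped (never padded),
    as are trials overlapping marked-bad samples by more than
    ``bad_fraction`` (default: any overlap). No baseline subtraction is
    performed unless ``baseline`` gives a window.
    """
    t_min, t_max = window
    if not (t_min <= 0.0 <= t_max):
        raise ValueError("epoch window must contain time 0")
    trigger_samples = np.asarray(trigger_samples, dtype=int)
    i0 = int(round(t_min * eeg.rate))
    i1 = int(round(t_max * eeg.rate))
    rel = np.arange(i0, i1 + 1)
    times = rel / eeg.rate

    if metadata is None:
        metadata = pd.DataFrame(index=range(len(trigger_samples)))
    metadata = metadata.reset_index(drop=True)

    starts = trigger_samples + i0
    stops = trigger_samples + i1
    in_bounds = (starts >= 0) & (stops < eeg.n_samples)
    n_oob = int(np.sum(~in_bounds))
    if n_oob:
        logger.info("dropping %d trials whose window leaves the recording", n_oob)

    keep = []
    n_bad = 0
    bad = eeg.bad_mask
    cum_bad = np.concatenate([[0], np.cumsum(bad)])
    win_len = len(rel)
    for k in np.flatnonzero(in_bounds):
        overlap = cum_bad[stops[k] + 1] - cum_bad[starts[k]]
        if overlap / win_len > bad_fraction or (bad_fraction == 0.0 and overlap > 0):
            n_bad += 1
            continue
        keep.append(k)
    if n_bad:
        logger.info("dropping %d trials overlapping bad segments", n_bad)
    keep = np.asarray(keep, dtype=int)
    if len(keep) == 0:
        logger.warning("no trials survived epoch extraction")
        data = np.empty((0, eeg.data.shape[0], win_len))
        return EpochSet(data, times, alignment, metadata.iloc[:0], tuple(eeg.labels))

    data = np.stack([eeg.data[:, starts[k] : stops[k] + 1] for k in keep])
    if baseline is not None:
        b0, b1 = baseline
        sel = (times >= b0) & (times <= b1)
        data = data - data[:, :, sel].mean(axis=2, keepdims=True)
    return EpochSet(data, times, alignment, metadata.iloc[keep], tuple(eeg.labels))


def average_erp(epochs: EpochSet, by: str = "category") -> dict[str, Erp]:
    """Two-stage grand average: within subject, then unweighted across subjects.

    Returns one :class:`Erp` per value of the ``by`` metadata column.
    Subjects lacking trials in a category are excluded from that
    category's grand mean (logged). Without a ``subject`` column the data
    are treated as one subject.
    """
    md = epochs.metadata
    if by not in md.columns:
        raise ValueError(f"metadata has no {by!r} column")
    subjects = md["subject"] if "subject" in md.columns else pd.Series(0, index=md.index)
    out = {}
    all_subjects = subjects.unique()
    for cat, grp in md.groupby(by, sort=False):
        per_subject = []
        for s, sgrp in grp.groupby(subjects.loc[grp.index]):
            idx = np.flatnonzero(md.index.isin(sgrp.index))
            per_subject.append(epochs.data[idx].mean(axis=0))
        n_missing = len(all_subjects) - len(per_subject)
        if n_missing:
            logger.info("category %r: %d subjects without trials excluded", cat, n_missing)
        if not per_subject:
            raise ValueError(f"no subject has trials in category {cat!r}")
        stack = np.stack(per_subject)
        sem = (
            stack.std(axis=0, ddof=1) / np.sqrt(len(stack)) if len(stack) > 1 else None
        )
        out[cat] = Erp(
            mean=stack.mean(axis=0),
            times=epochs.times,
            n_subjects=len(per_subject),
            sem=sem,
            labels=epochs.labels,
        )
    return out


def sorted_trial_image(
    epochs: EpochSet,
    channel: str,
    sigma_y: float = 2.0,
    sigma_x: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Duration-sorted single-trial image at one channel.

    Fixation-aligned trials are sorted by descending preceding-saccade
    duration (longest on top) and smoothed with an anisotropic Gaussian
    (``sigma_y`` across trials, ``sigma_x`` across samples; zeros are the
    identity). Returns ``(image, overlay, order)`` where ``overlay`` is
    the per-row saccade-onset time (-duration, seconds) and ``order`` the
    trial permutation applied.
    """
    if "saccade_duration" not in epochs.metadata.columns:
        raise ValueError("trials carry no saccade_duration metadata")
    durations = epochs.metadata["saccade_duration"].to_numpy(dtype=float)
    if np.any(~np.isfinite(durations)):
        raise ValueError("saccade durations contain non-finite values")
    ch = list(epochs.labels).index(channel) if epochs.labels else int(channel)
    order = np.argsort(-durations, kind="stable")
    img = epochs.data[order, ch, :]
    if sigma_y > 0 or sigma_x > 0:
        img = gaussian_filter(img, sigma=(sigma_y, sigma_x), mode="nearest")
    overlay = -durations[order]
    return img, overlay, order
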