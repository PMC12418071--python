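"""End-to-end orchestration: cohort -> detection -> alignment -> ERPs -> inference.

Glue over the stage modules, mirroring how a recorded study would be
processed: detect gaze events on the (drifting, motion-contaminated)
gaze stream, label fixations with their stimulus category, map saccade
onsets onto EEG samples through the estimated clock-drift model, fit the
overlap-correcting FIR model per subject, and test category differences
across subjects with TFCE permutation inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import DriftModel, estimate_drift, events_to_samples
from .deconv import DeconvResult, build_design, fit_deconvolution
from .epochs import (
    CATEGORIES,
    WINDOW_DECONV,
    WINDOW_RAW,
    EpochSet,
    assign_saccade_category,
    extract_epochs,
)
from .gaze import FIXATION, SACCADE, GazeEvent, detect_gaze_events
from .montage import channel_adjacency, channel_positions
from .simulate import GroundTruth, KernelSpec, Session
from .summaries import events_to_frame
from .tfce import TfceResult, cluster_summary, permutation_test

logger = logging.getLogger(__name__)


def label_fixations_from_truth(
    events: list[GazeEvent], truth: GroundTruth, drift: DriftModel | None = None
) -> list[GazeEvent]:
    """Assign stimulus categories to detected fixations by ground-truth overlap.

    In recorded data the category comes from collider hit-testing and is
    an input column; for synthetic sessions the generator's event table
    plays that role. Each detected fixation inherits the category of the
    true fixation it overlaps most (detected times are mapped onto the
    true timeline through ``drift`` when given).
    """
    gt = truth.fixations
    starts = gt["onset_s"].to_numpy()
    stops = gt["offset_s"].to_numpy()
    cats = gt["category"].to_numpy()
    for ev in events:
        if ev.kind != FIXATION:
            continue
        a, b = ev.onset, ev.offset
        if drift is not None:
            a = drift.offset + drift.rate * a
            b = drift.offset + drift.rate * b
        overlap = np.minimum(stops, b) - np.maximum(starts, a)
        k = int(np.argmax(overlap))
        ev.category = cats[k] if overlap[k] > 0 else "none"
    return events


@dataclass
class SubjectResult:
    subject: int
    events: pd.DataFrame
    drift: DriftModel
    epochs_fix: EpochSet
    epochs_sacc: EpochSet
    deconv: DeconvResult


@dataclass
class CohortResult:
    subjects: list
    maps: np.ndarray  # subjects x conditions x channels x lags
    lags: np.ndarray
    labels: tuple
    tfce: TfceResult
    clusters: list
    contributions: pd.DataFrame


def process_session(
    session: Session,
    lam: float = 5.0,
    interval_len: float = 10.0,
    window_raw: tuple = WINDOW_RAW,
    window_deconv: tuple = WINDOW_DECONV,
) -> SubjectResult:
    """Detection, drift correction, epoching and deconvolution for one subject."""
    trace = session.trace
    params = session.params
    events = detect_gaze_events(trace, interval_len=interval_len, lam=lam, correct=True)
    # drift model from the first/last timestamps of the two streams: the
    # EEG clock is the reference and both streams span the same interval
    true_last = (len(trace) - 1) / params.gaze_rate
    drift = estimate_drift(trace.time[0], trace.time[-1], 0.0, true_last)
    events = label_fixations_from_truth(events, session.truth, drift=drift)
    events = assign_saccade_category(events)

    ev_df = events_to_frame(events)
    is_trial = (ev_df["kind"] == SACCADE) & (ev_df["category"] != "none")
    sacc = ev_df[is_trial]
    fix_after = ev_df.shift(-1)[is_trial]  # the fixation each saccade leads into

    n_samples = session.eeg.n_samples
    sacc_idx, kept_s = events_to_samples(
        sacc["onset_s"].to_numpy(), drift, params.eeg_rate, n_samples=n_samples
    )
    fix_idx, kept_f = events_to_samples(
        fix_after["onset_s"].to_numpy(), drift, params.eeg_rate, n_samples=n_samples
    )
    both = kept_s & kept_f  # the same trial set for both alignments
    md = sacc.loc[both, ["category", "duration_s", "amplitude_deg"]].rename(
        columns={"duration_s": "saccade_duration", "amplitude_deg": "saccade_amplitude"}
    )
    md["subject"] = session.subject
    md = md.reset_index(drop=True)
    sacc_idx = sacc_idx[both[kept_s]]
    fix_idx = fix_idx[both[kept_f]]

    ep_sacc = extract_epochs(
        session.eeg, sacc_idx, window_raw, metadata=md, alignment="saccade"
    )
    ep_fix = extract_epochs(
        session.eeg, fix_idx, window_raw, metadata=md, alignment="fixation"
    )
    design = build_design(
        sacc_idx, md["category"].to_numpy(), n_samples, params.eeg_rate,
        window=window_deconv,
        mask=session.eeg.bad_mask if session.eeg.bad_mask.any() else None,
    )
    dec = fit_deconvolution(session.eeg, design)
    return SubjectResult(
        subject=session.subject,
        events=ev_df,
        drift=drift,
        epochs_fix=ep_fix,
        epochs_sacc=ep_sacc,
        deconv=dec,
    )


def subject_condition_maps(results: list[SubjectResult]) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Stack per-subject deconvolved kernels into subjects x conditions x channels x lags.

    Subjects with an undefined (event-free) category are excluded, logged.
    """
    maps, lags, labels = [], None, None
    n_drop = 0
    for r in results:
        if np.any(~np.isfinite(r.deconv.kernels)):
            n_drop += 1
            continue
        maps.append(r.deconv.kernels)
        lags, labels = r.deconv.lags, r.deconv.labels
    if n_drop:
        logger.info("excluding %d subjects with an event-free category", n_drop)
    if len(maps) < 2:
        raise ValueError("fewer than 2 complete subjects")
    return np.stack(maps), lags, labels


def run_cohort(
    sessions: list[Session],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    lam: float = 5.0,
    interval_len: float = 10.0,
) -> CohortResult:
    """Full pipeline over a cohort of sessions."""
    results = [process_session(s, lam=lam, interval_len=interval_len) for s in sessions]
    maps, lags, labels = subject_condition_maps(results)
    adj = channel_adjacency(channel_positions(labels))
    tfce = permutation_test(maps, adj, n_perm=n_perm, alpha=alpha, seed=seed)
    clusters, contributions = cluster_summary(
        tfce, maps, adj, lags, labels=labels, condition_order=CATEGORIES
    )
    return CohortResult(
        subjects=results,
        maps=maps,
        lags=lags,
        labels=labels,
        tfce=tfce,
        clusters=clusters,
        contributions=contributions,
    )


def injected_effect_support(
    kernels: KernelSpec,
    lags_target: np.ndarray,
    rate: float,
    cat_a: str = "head",
    cat_b: str = "background",
    frac: float = 0.5,
) -> np.ndarray:
    """Boolean (channels x lags_target) support of the injected category effect.

    Cells where the true |kernel difference| reaches at least ``frac`` of
    its maximum, embedded on the analysis lag axis.
    """
    ci = {c: i for i, c in enumerate(kernels.categories)}
    diff = np.abs(kernels.kernels[ci[cat_a]] - kernels.kernels[ci[cat_b]])
    out = np.zeros((diff.shape[0], len(lags_target)), dtype=bool)
    src_idx = np.round(kernels.lags * rate).astype(int)
    tgt_idx = np.round(np.asarray(lags_target) * rate).astype(int)
    pos = {v: i for i, v in enumerate(tgt_idx)}
    thresh = frac * diff.max()
    for j, sidx in enumerate(src_idx):
        if sidx in pos:
            out[:, pos[sidx]] = diff[:, j] >= thresh
    return out
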