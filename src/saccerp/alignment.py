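"""Linear clock alignment of the gaze and EEG streams.

Independently clocked acquisition systems drift apart slowly and, to
first order, linearly. The correction mirrors common practice for LSL-
style recordings: compute the offset between the first timestamps of the
two streams and between the last ones, and rescale the gaze timeline so
both endpoints coincide with the EEG timeline. The same model maps every
gaze event onto an EEG sample index, identically for fixation- and
saccade-onset triggers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class DriftModel:
    """t_eeg = offset + rate * t_eye."""

    offset: float
    rate: float
    residual_check: float = 0.0  # largest post-correction anchor deviation, s

    def __post_init__(self):
        if not self.rate > 0:
            raise ValueError("drift rate must be positive")


def estimate_drift(
    eye_first: float, eye_last: float, eeg_first: float, eeg_last: float
) -> DriftModel:
    """Two-anchor (endpoints-only) linear drift estimate.

    After correction the gaze endpoints coincide with the EEG endpoints
    exactly, by construction.
    """
    if eye_last <= eye_first or eeg_last <= eeg_first:
        raise ValueError("streams must have positive duration (last > first)")
    rate = (eeg_last - eeg_first) / (eye_last - eye_first)
    offset = eeg_first - rate * eye_first
    model = DriftModel(offset=offset, rate=rate)
    resid = max(
        abs(apply_drift(model, eye_first) - eeg_first),
        abs(apply_drift(model, eye_last) - eeg_last),
    )
    model.residual_check = float(resid)
    return model


def estimate_drift_multi(eye_times, eeg_times) -> DriftModel:
    """Least-squares drift estimate over multiple shared anchors.

    A robustness variant of :func:`estimate_drift` for recordings with
    more than two trustworthy synchronization events; ``residual_check``
    reports the largest post-fit anchor deviation and flags sessions
    whose drift is not linear.
    """
    eye = np.asarray(eye_times, dtype=float)
    eeg = np.asarray(eeg_times, dtype=float)
    if eye.shape != eeg.shape or eye.size < 2:
        raise ValueError("need >= 2 paired anchors of equal length")
    rate, offset = np.polyfit(eye, eeg, 1)
    model = DriftModel(offset=float(offset), rate=float(rate))
    model.residual_check = float(np.max(np.abs(apply_drift(model, eye) - eeg)))
    return model


def apply_drift(model: DriftModel, times):
    """Map gaze-clock times onto the EEG clock (vectorized, monotone)."""
    return model.offset + model.rate * np.asarray(times, dtype=float)


def invert_drift(model: DriftModel) -> DriftModel:
    """EEG-clock -> gaze-clock model; composing the two is the identity."""
    return DriftModel(offset=-model.offset / model.rate, rate=1.0 / model.rate,
                      residual_check=model.residual_check)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (documented convention; numpy rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def events_to_samples(
    event_times,
    model: DriftModel,
    eeg_rate: float,
    eeg_t0: float = 0.0,
    n_samples: int | None = None,
):
    """Map event times (gaze clock) to EEG sample indices.

    index = round((t' - eeg_t0) * eeg_rate) with round-half-away-from-zero.
    Events falling outside [0, n_samples) are dropped with a logged count.
    Returns ``(indices, kept_mask)``.
    """
    t = apply_drift(model, event_times)
    idx = _round_half_away((t - eeg_t0) * eeg_rate).astype(int)
    keep = idx >= 0
    if n_samples is not None:
        keep &= idx < n_samples
    n_drop = int(np.sum(~keep))
    if n_drop:
        logger.info("dropping %d events outside the EEG span", n_drop)
    if not np.any(keep):
        raise ValueError("all events fall outside the EEG span")
    return idx[keep], keep
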