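"""Synthetic free-viewing VR sessions: scanpath, head motion, and EEG.

The generator emulates the statistical structure a saccade-onset ERP
analysis relies on, so that every downstream stage is testable without
recorded data:

* an alternating fixation/saccade sequence whose per-category saccade
  duration and amplitude laws are log-normal with configurable medians
  (defaults follow published free-viewing VR values: background saccades
  are the longest and largest, head saccades the shortest and smallest);
* amplitude and duration coupled through a shared latent factor (the
  main-sequence correlation);
* raised-cosine saccadic speed profiles and low-amplitude fixational
  jitter;
* slow observer translation that contaminates the gaze-in-world signal
  with compensatory rotation (the component the detection module removes);
* a linear clock drift between the gaze and EEG timelines;
* EEG built as a linear superposition of saccade-locked kernels — a
  posterior P100-like lobe common to all categories plus a later
  category-specific deflection — over 1/f^alpha background noise, so
  that temporally close events overlap by construction.

All randomness flows from integer seeds through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .epochs import CATEGORIES, EEGRecording, EpochSet
from .gaze import GazeTrace, vec_to_angles
from .montage import CHANNELS_32, channel_positions, posterior_gain

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameters

def _cat_dict(background, body, head):
    return {"background": background, "body": body, "head": head}


@dataclass
class SessionParams:
    """Generator configuration for one synthetic session.

    Medians are per category (background, body, head). The default
    saccade/fixation medians are the published free-viewing values; the
    within-session MADs are this package's own realistic spreads (the
    published MADs describe between-subject variation of per-subject
    medians and belong to the cohort level, not the trial level).
    """

    duration: float = 1800.0  # seconds
    gaze_rate: float = 90.0  # Hz
    eeg_rate: float = 500.0  # Hz
    n_channels: int = 32
    # trial mix: observed trial counts 3968 : 741 : 151
    category_mix: dict = field(
        default_factory=lambda: _cat_dict(0.81646, 0.15247, 0.03107)
    )
    saccade_dur_med: dict = field(default_factory=lambda: _cat_dict(0.076, 0.066, 0.056))
    saccade_dur_mad: dict = field(default_factory=lambda: _cat_dict(0.012, 0.010, 0.008))
    saccade_amp_med: dict = field(default_factory=lambda: _cat_dict(12.119, 7.212, 5.35))
    saccade_amp_mad: dict = field(default_factory=lambda: _cat_dict(4.0, 2.5, 1.8))
    fixation_dur_med: dict = field(default_factory=lambda: _cat_dict(0.186, 0.200, 0.178))
    fixation_dur_mad: dict = field(default_factory=lambda: _cat_dict(0.06, 0.06, 0.06))
    dur_amp_corr: float = 0.8  # latent coupling, induces the main sequence
    target_dist_med: float = 5.209  # m, median gaze distance
    target_dist_mad: float = 2.591
    head_motion_amp: float = 1.0  # RMS translational speed, m/s
    jitter_deg: float = 0.05  # fixational jitter (angular SD per sample)
    drift_rate: float = 0.011 / 1800.0  # clock-rate deviation (11 ms over 30 min)
    drift_offset: float = 0.0  # s
    noise_alpha: float = 1.0  # spectral exponent of background EEG
    noise_scale: float = 8.0  # microvolt RMS of background EEG
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for r in (self.gaze_rate, self.eeg_rate):
            if r <= 0:
                raise ValueError("sampling rates must be positive")
        total = sum(self.category_mix.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("category_mix must sum to 1")
        if any(p < 0 for p in self.category_mix.values()):
            raise ValueError("category_mix proportions must be non-negative")


@dataclass
class KernelSpec:
    """Saccade-locked response kernels, category x channel x lag (microvolt)."""

    lags: np.ndarray  # seconds, uniform at the EEG rate
    kernels: np.ndarray  # (n_categories, n_channels, n_lags)
    categories: tuple = CATEGORIES
    fixation_kernel: np.ndarray | None = None  # optional (n_channels, n_lags)

    def __post_init__(self):
        if not np.all(np.isfinite(self.kernels)):
            raise ValueError("kernels must be finite")
        if self.kernels.shape[0] != len(self.categories):
            raise ValueError("kernel count must match categories")
        if self.kernels.shape[2] != len(self.lags):
            raise ValueError("kernel lag axis mismatch")

    def scaled(self, factor: float) -> "KernelSpec":
        fx = None if self.fixation_kernel is None else self.fixation_kernel * factor
        return KernelSpec(self.lags, self.kernels * factor, self.categories, fx)


@dataclass
class GroundTruth:
    """True events, drift, and kernels behind one synthetic session."""

    events: pd.DataFrame  # onset_s, offset_s, kind, category, duration_s, amplitude_deg
    drift_rate: float = 1.0
    drift_offset: float = 0.0
    kernels: KernelSpec | None = None

    @property
    def saccades(self) -> pd.DataFrame:
        return self.events[self.events["kind"] == "saccade"]

    @property
    def fixations(self) -> pd.DataFrame:
        return self.events[self.events["kind"] == "fixation"]


@dataclass
class Session:
    subject: int
    params: SessionParams
    trace: GazeTrace
    truth: GroundTruth
    eeg: EEGRecording
    kernels: KernelSpec


SessionSet = list  # list[Session]


# ---------------------------------------------------------------------------
# distribution helpers

def lognormal_sigma(median: float, mad: float) -> float:
    """Log-scale sigma such that the log-normal has the given median and MAD."""
    if mad == 0:
        return 0.0
    r = mad / median
    if r >= 1:
        raise ValueError("MAD must be smaller than the median for a log-normal law")

    def gap(sigma):
        return norm.cdf(np.log1p(r) / sigma) - norm.cdf(np.log1p(-r) / sigma) - 0.5

    return brentq(gap, 1e-9, 20.0)


def p100_waveform(t, amp: float = 6.0, latency: float = 0.115, width: float = 0.02):
    """Analytic P100-like lobe: a Gaussian bump at ``latency`` after saccade onset."""
    t = np.asarray(t, dtype=float)
    return amp * np.exp(-((t - latency) ** 2) / (2.0 * width**2))


def p100_half_rise(latency: float = 0.115, width: float = 0.02) -> float:
    """Closed-form time of the half-maximum point on the rising slope (zero reference)."""
    return latency - width * np.sqrt(2.0 * np.log(2.0))


def default_kernels(
    eeg_rate: float = 500.0,
    labels=CHANNELS_32,
    p100_amp: float = 6.0,
    head_amp: float = -3.0,
    body_amp: float = -0.5,
    p100_latency: float = 0.115,
    p100_width: float = 0.02,
    effect_latency: float = 0.175,
    effect_width: float = 0.035,
) -> KernelSpec:
    """Default saccade-locked kernels on the synthetic montage.

    All categories share a posterior P100-like positive lobe; the head
    (and, weakly, body) category adds a later posterior deflection inside
    the 0.10-0.25 s window, mimicking a face-sensitive component.
    """
    lags = np.arange(round(-0.1 * eeg_rate), round(0.5 * eeg_rate) + 1) / eeg_rate
    pos = channel_positions(labels)
    g_p100 = posterior_gain(pos, foci=("PO7", "PO8"), width=0.45)
    g_eff = posterior_gain(pos, foci=("PO7", "PO8"), width=0.5)
    p100 = p100_waveform(lags, p100_amp, p100_latency, p100_width)
    effect = np.exp(-((lags - effect_latency) ** 2) / (2.0 * effect_width**2))
    k_bg = g_p100[:, None] * p100[None, :]
    k_body = k_bg + body_amp * g_eff[:, None] * effect[None, :]
    k_head = k_bg + head_amp * g_eff[:, None] * effect[None, :]
    return KernelSpec(lags=lags, kernels=np.stack([k_bg, k_body, k_head]))


# ---------------------------------------------------------------------------
# scanpath generation

def _head_trajectory(times: np.ndarray, amp: float, rng: np.random.Generator):
    """Smooth seated-observer translation: sums of <=0.3 Hz sinusoids.

    ``amp`` is the RMS translational speed in m/s (vertical bob scaled
    down); returns (n, 3) positions in meters.
    """
    n = len(times)
    pos = np.zeros((n, 3))
    if amp == 0:
        return pos
    axis_scale = np.array([1.0, 0.2, 1.0])  # x, y(up), z
    n_comp = 3
    freqs = rng.uniform(0.02, 0.3, size=(3, n_comp))
    phases = rng.uniform(0, 2 * np.pi, size=(3, n_comp))
    weights = rng.uniform(0.5, 1.0, size=(3, n_comp)) * axis_scale[:, None]
    # scale position amplitudes so the summed RMS speed equals `amp`
    omega = 2 * np.pi * freqs
    rms = np.sqrt(np.sum((weights * omega) ** 2) / 2.0)
    a = weights * (amp / rms)
    for ax in range(3):
        pos[:, ax] = np.sum(
            a[ax][None, :] * np.sin(omega[ax][None, :] * times[:, None] + phases[ax]),
            axis=1,
        )
    return pos


def _head_at(t: float, times: np.ndarray, head: np.ndarray) -> np.ndarray:
    """Linear interpolation of the head path at a continuous time."""
    return np.array([np.interp(t, times, head[:, k]) for k in range(3)])


def _slerp(a: np.ndarray, b: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit-vector arrays a, b at fractions s."""
    dot = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    ang = np.arccos(dot)
    out = np.empty_like(a)
    small = ang < 1e-9
    sa = np.sin(ang)
    with np.errstate(invalid="ignore", divide="ignore"):
        w0 = np.sin((1.0 - s) * ang) / sa
        w1 = np.sin(s * ang) / sa
    out = w0[..., None] * a + w1[..., None] * b
    if np.any(small):
        out[small] = a[small]
    return out


_AZ_LIM = 55.0
_EL_LIM = 32.0


def _pick_target_direction(u: np.ndarray, amp_deg: float, rng) -> np.ndarray:
    """Rotate gaze direction ``u`` by ``amp_deg`` along a random tangent,
    keeping the result inside the comfortable viewing cone."""
    amp = np.deg2rad(amp_deg)
    # orthonormal tangent basis at u
    ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, u)
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(np.array([1.0, 0.0, 0.0]), u)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    for _ in range(40):
        psi = rng.uniform(0, 2 * np.pi)
        tangent = np.cos(psi) * e1 + np.sin(psi) * e2
        v = np.cos(amp) * u + np.sin(amp) * tangent
        az, el = vec_to_angles(v)
        if abs(az) <= _AZ_LIM and abs(el) <= _EL_LIM:
            return v
    # aim back toward straight ahead
    center = np.array([0.0, 0.0, 1.0])
    tangent = center - np.dot(center, u) * u
    nrm = np.linalg.norm(tangent)
    tangent = e1 if nrm < 1e-9 else tangent / nrm
    return np.cos(amp) * u + np.sin(amp) * tangent


def _draw_events(params: SessionParams, rng) -> pd.DataFrame:
    """Draw the alternating fixation/saccade schedule and its marginals."""
    cats = list(CATEGORIES)
    probs = np.array([params.category_mix[c] for c in cats])
    sig_d = {c: lognormal_sigma(params.saccade_dur_med[c], params.saccade_dur_mad[c]) for c in cats}
    sig_a = {c: lognormal_sigma(params.saccade_amp_med[c], params.saccade_amp_mad[c]) for c in cats}
    sig_f = {c: lognormal_sigma(params.fixation_dur_med[c], params.fixation_dur_mad[c]) for c in cats}
    rho = params.dur_amp_corr

    rows = []
    t = 0.0
    cat = cats[rng.choice(len(cats), p=probs)]
    fdur = params.fixation_dur_med[cat] * np.exp(sig_f[cat] * rng.standard_normal())
    while True:
        if t + fdur > params.duration:
            fdur = params.duration - t
            if fdur > 1e-6:
                rows.append((t, t + fdur, "fixation", cat, fdur, np.nan))
            break
        rows.append((t, t + fdur, "fixation", cat, fdur, np.nan))
        t += fdur
        # saccade into the next fixation; it carries that fixation's category
        nxt = cats[rng.choice(len(cats), p=probs)]
        z0 = rng.standard_normal()
        z1 = rng.standard_normal()
        sdur = params.saccade_dur_med[nxt] * np.exp(sig_d[nxt] * z0)
        samp = params.saccade_amp_med[nxt] * np.exp(
            sig_a[nxt] * (rho * z0 + np.sqrt(1 - rho**2) * z1)
        )
        if t + sdur > params.duration:
            break
        rows.append((t, t + sdur, "saccade", nxt, sdur, samp))
        t += sdur
        cat = nxt
        fdur = params.fixation_dur_med[cat] * np.exp(sig_f[cat] * rng.standard_normal())
    if len(rows) < 3:
        raise ValueError("session duration too short to hold one fixation+saccade")
    return pd.DataFrame(
        rows, columns=["onset_s", "offset_s", "kind", "category", "duration_s", "amplitude_deg"]
    )


def generate_scanpath(params: SessionParams, rng=None) -> tuple[GazeTrace, GroundTruth]:
    """Generate one session's gaze trace and its ground truth.

    The gaze-in-world direction is the direction from the (moving) head
    to the current gaze point; fixations hold a world point fixed, so
    observer translation induces exactly the compensatory rotation that
    the translational-motion correction is meant to remove.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    events = _draw_events(params, rng)
    n = int(np.floor(params.duration * params.gaze_rate)) + 1
    times = np.arange(n) / params.gaze_rate
    head = _head_trajectory(times, params.head_motion_amp, rng)

    sig_dist = lognormal_sigma(params.target_dist_med, params.target_dist_mad)

    az = np.empty(n)
    el = np.empty(n)
    dist = np.empty(n)
    g = np.empty((n, 3))

    # initial target straight ahead
    h0 = head[0]
    d_cur = params.target_dist_med * np.exp(sig_dist * rng.standard_normal())
    q_cur = h0 + d_cur * np.array([0.0, 0.0, 1.0])

    onsets = events["onset_s"].to_numpy()
    sample_of = np.searchsorted(times, onsets - 1e-12)
    sample_end = np.r_[sample_of[1:], n]

    for i, row in enumerate(events.itertuples(index=False)):
        a, b = sample_of[i], sample_end[i]
        if a >= b:
            continue
        h_seg = head[a:b]
        if row.kind == "fixation":
            rel = q_cur - h_seg
            dist[a:b] = np.linalg.norm(rel, axis=1)
            g[a:b] = rel / dist[a:b, None]
        else:  # saccade
            h_on = _head_at(row.onset_s, times, head)
            u = q_cur - h_on
            u /= np.linalg.norm(u)
            v = _pick_target_direction(u, row.amplitude_deg, rng)
            d_new = params.target_dist_med * np.exp(sig_dist * rng.standard_normal())
            q_new = h_on + d_new * v
            tau = (times[a:b] - row.onset_s) / row.duration_s
            tau = np.clip(tau, 0.0, 1.0)
            s = tau - np.sin(2 * np.pi * tau) / (2 * np.pi)  # raised-cosine profile
            rel_old = q_cur - h_seg
            rel_new = q_new - h_seg
            d_old_i = np.linalg.norm(rel_old, axis=1)
            d_new_i = np.linalg.norm(rel_new, axis=1)
            g[a:b] = _slerp(rel_old / d_old_i[:, None], rel_new / d_new_i[:, None], s)
            dist[a:b] = (1 - s) * d_old_i + s * d_new_i
            q_cur = q_new

    if params.jitter_deg > 0:
        # isotropic tangent-plane jitter, small-angle
        jit = np.deg2rad(params.jitter_deg) * rng.standard_normal((n, 2))
        ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(np.broadcast_to(ref, g.shape), g)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(g, e1)
        g = g + jit[:, :1] * e1 + jit[:, 1:] * e2
        g /= np.linalg.norm(g, axis=1, keepdims=True)

    az, el = vec_to_angles(g)
    trace = GazeTrace(
        time=times,
        az=az,
        el=el,
        rate=params.gaze_rate,
        head_pos=head,
        head_yaw=np.zeros(n),
        gaze_dist=dist,
    )
    truth = GroundTruth(events=events)
    return trace, truth


# ---------------------------------------------------------------------------
# EEG forward model

def pink_noise(n: int, alpha: float, rng, rate: float = 1.0) -> np.ndarray:
    """Unit-RMS noise with power spectrum proportional to 1/f^alpha."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spectrum = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    shape = np.zeros(len(freqs))
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spectrum * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_eeg(
    truth: GroundTruth,
    kernels: KernelSpec,
    params: SessionParams,
    rng=None,
    labels=None,
) -> EEGRecording:
    """Superpose saccade-locked kernels over 1/f^alpha noise.

    Responses of temporally close events sum linearly — the overlap the
    deconvolution stage corrects is produced here by construction.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed + 1))
    if not np.all(np.isfinite(kernels.kernels)):
        raise ValueError("kernels must not contain NaN")
    rate = params.eeg_rate
    n = int(round(params.duration * rate)) + 1
    n_ch = kernels.kernels.shape[1]
    if labels is None:
        labels = CHANNELS_32[:n_ch]
    data = np.zeros((n_ch, n))
    lag_idx = np.round(kernels.lags * rate).astype(int)
    cat_index = {c: i for i, c in enumerate(kernels.categories)}

    sacc = truth.saccades
    if len(sacc) and (
        sacc["onset_s"].min() < -1e-9 or sacc["onset_s"].max() > params.duration + 1e-9
    ):
        raise ValueError("ground-truth events must fall inside [0, duration]")
    for row in sacc.itertuples(index=False):
        ci = cat_index.get(row.category)
        if ci is None:
            continue
        s0 = int(round(row.onset_s * rate))
        idx = s0 + lag_idx
        ok = (idx >= 0) & (idx < n)
        data[:, idx[ok]] += kernels.kernels[ci][:, ok]
    if kernels.fixation_kernel is not None:
        for row in truth.fixations.itertuples(index=False):
            s0 = int(round(row.onset_s * rate))
            idx = s0 + lag_idx
            ok = (idx >= 0) & (idx < n)
            data[:, idx[ok]] += kernels.fixation_kernel[:, ok]
    if params.noise_scale > 0:
        for ch in range(n_ch):
            data[ch] += params.noise_scale * pink_noise(n, params.noise_alpha, rng, rate)
    return EEGRecording(data=data, rate=rate, labels=tuple(labels))


# ---------------------------------------------------------------------------
# clock drift and cohorts

def apply_clock_drift(trace: GazeTrace, rate: float, offset: float = 0.0) -> GazeTrace:
    """Re-stamp the gaze timeline as t' = offset + rate * t (samples untouched)."""
    if rate <= 0:
        raise ValueError("clock rate must be positive")
    return replace(trace, time=offset + rate * trace.time)


def generate_session(
    params: SessionParams, kernels: KernelSpec | None = None, subject: int = 0
) -> Session:
    """Scanpath -> EEG -> clock drift for one subject."""
    ss = np.random.SeedSequence(params.seed)
    rng_gaze, rng_eeg = (np.random.default_rng(s) for s in ss.spawn(2))
    if kernels is None:
        kernels = default_kernels(params.eeg_rate)
        if params.n_channels != kernels.kernels.shape[1]:
            lab = CHANNELS_32[: params.n_channels]
            kernels = default_kernels(params.eeg_rate, labels=lab)
    trace, truth = generate_scanpath(params, rng_gaze)
    truth.kernels = kernels
    eeg = generate_eeg(truth, kernels, params, rng_eeg)
    drift_rate = 1.0 + params.drift_rate
    truth.drift_rate = drift_rate
    truth.drift_offset = params.drift_offset
    trace = apply_clock_drift(trace, drift_rate, params.drift_offset)
    return Session(subject=subject, params=params, trace=trace, truth=truth,
                   eeg=eeg, kernels=kernels)


def generate_cohort(
    n_subjects: int,
    params: SessionParams,
    between_subject_sd: float = 0.2,
    kernels: KernelSpec | None = None,
) -> SessionSet:
    """Generate a cohort with per-subject parameter heterogeneity.

    Each subject draws, once, a kernel-amplitude factor ~ N(1, sd), a
    perturbed category mix, and log-normal perturbations of the event-
    duration/amplitude medians; subject seeds derive reproducibly from
    the master seed.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    master = np.random.SeedSequence(params.seed)
    pert_rng = np.random.default_rng(master.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in master.spawn(n_subjects + 1)[1:]]
    if kernels is None:
        kernels = default_kernels(params.eeg_rate, labels=CHANNELS_32[: params.n_channels])
    sd = between_subject_sd
    sessions = []
    for s in range(n_subjects):
        amp_factor = max(0.2, 1.0 + sd * pert_rng.standard_normal())
        mix = np.array([params.category_mix[c] for c in CATEGORIES])
        mix = mix * np.exp(sd * pert_rng.standard_normal(len(mix)))
        mix = mix / mix.sum()
        med_jit = np.exp(0.5 * sd * pert_rng.standard_normal(3))
        p_s = replace(
            params,
            seed=child_seeds[s],
            category_mix=dict(zip(CATEGORIES, mix)),
            saccade_dur_med={c: v * med_jit[0] for c, v in params.saccade_dur_med.items()},
            saccade_amp_med={c: v * med_jit[1] for c, v in params.saccade_amp_med.items()},
            fixation_dur_med={c: v * med_jit[2] for c, v in params.fixation_dur_med.items()},
        )
        sessions.append(generate_session(p_s, kernels=kernels.scaled(amp_factor), subject=s))
    return sessions


# ---------------------------------------------------------------------------
# reduced epoch-level generator for temporal-stability studies

def simulate_stability_cohort(
    n_subjects: int = 20,
    n_trials: int = 150,
    dur_mean: float = 0.055,
    dur_sd: float = 0.03,
    rate: float = 500.0,
    window: tuple[float, float] = (-0.3, 0.5),
    noise_sd: float = 20.0,
    kernel_amp: float = 6.0,
    seed: int = 0,
) -> tuple[EpochSet, EpochSet]:
    """Fixation- and saccade-aligned epoch pairs with a purely saccade-locked P100.

    Each trial is one realization of kernel + white noise on a continuous
    axis; the fixation-aligned epoch is the same realization sampled with
    an integer-sample shift equal to the trial's saccade duration, so the
    time-shift duality between alignments holds exactly. This reduced
    generator carries the statistical structure the half-maximum
    stability statistic depends on (duration spread, saccade locking,
    trial noise) without full-session synthesis.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    w0, w1 = window
    i0, i1 = round(w0 * rate), round(w1 * rate)
    times = np.arange(i0, i1 + 1) / rate
    nwin = len(times)
    max_shift = int(np.ceil(0.12 * rate))
    ext_times = np.arange(i0, i1 + max_shift + 1) / rate

    fix_data, sacc_data, meta = [], [], []
    for s in range(n_subjects):
        durs = rng.normal(dur_mean, dur_sd, size=n_trials)
        durs = np.clip(durs, 0.005, 0.1)
        shifts = np.round(durs * rate).astype(int)
        signal = p100_waveform(ext_times, amp=kernel_amp)
        for tr in range(n_trials):
            ext = signal + noise_sd * rng.standard_normal(len(ext_times))
            sacc_data.append(ext[:nwin])
            fix_data.append(ext[shifts[tr] : shifts[tr] + nwin])
            meta.append((s, shifts[tr] / rate))
    md = pd.DataFrame(meta, columns=["subject", "saccade_duration"])
    md["category"] = "background"
    fix = EpochSet(np.asarray(fix_data)[:, None, :], times, "fixation", md.copy(), ("PO7",))
    sacc = EpochSet(np.asarray(sacc_data)[:, None, :], times, "saccade", md.copy(), ("PO7",))
    return fix, sacc
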