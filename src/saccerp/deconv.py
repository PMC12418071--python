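"""FIR linear deconvolution of overlapping saccade-locked responses.

Free viewing produces events a few hundred milliseconds apart while the
neural response to each spans over a second, so naive epoch averages mix
the responses of neighboring events. The remedy is a time-expanded
("stick") linear model: one regressor per (category, lag) pair over a
-0.5..1.0 s lag window around every saccade onset, fit jointly by least
squares per channel. Without overlap the solution reduces to the simple
per-category average; with overlap it unmixes the summed responses.

No intercept column is used: the stick columns at every lag absorb the
mean response. Samples flagged bad contribute nothing to the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import lsmr

from .epochs import CATEGORIES, EEGRecording, WINDOW_DECONV, extract_epochs

logger = logging.getLogger(__name__)


@dataclass
class DeconvDesign:
    """Sparse time-expanded design matrix: samples x (categories * lags)."""

    matrix: sp.csr_matrix
    lags: np.ndarray  # seconds
    categories: tuple
    rate: float
    mask: np.ndarray | None  # True = excluded sample
    n_events: dict

    @property
    def n_lags(self) -> int:
        return len(self.lags)


@dataclass
class DeconvResult:
    """Per-category, per-channel response kernels from the overlap model."""

    kernels: np.ndarray  # (n_categories, n_channels, n_lags), microvolt
    lags: np.ndarray
    categories: tuple
    labels: tuple
    residual_var: np.ndarray  # per channel
    n_events: dict


def build_design(
    trigger_samples,
    categories,
    n_samples: int,
    rate: float,
    window: tuple[float, float] = WINDOW_DECONV,
    mask: np.ndarray | None = None,
    category_order: tuple = CATEGORIES,
) -> DeconvDesign:
    """Time-expanded stick coding of saccade onsets.

    Column (c, tau) holds a 1 at sample s iff an event of category c
    occurs at sample s - tau*rate. Rows of masked samples are zeroed so
    they contribute nothing to the loss.
    """
    trigger_samples = np.asarray(trigger_samples, dtype=int)
    categories = np.asarray(categories)
    if len(trigger_samples) == 0:
        raise ValueError("empty trigger list")
    if len(trigger_samples) != len(categories):
        raise ValueError("each trigger needs a category")
    unknown = set(categories) - set(category_order)
    if unknown:
        raise ValueError(f"categories outside the factor levels: {sorted(unknown)}")
    if np.any((trigger_samples < 0) | (trigger_samples >= n_samples)):
        raise ValueError("trigger samples out of range")
    lag_idx = np.arange(round(window[0] * rate), round(window[1] * rate) + 1)
    lags = lag_idx / rate
    n_lags = len(lag_idx)

    rows, cols = [], []
    n_events = {}
    for ci, cat in enumerate(category_order):
        ev = trigger_samples[categories == cat]
        n_events[cat] = len(ev)
        if len(ev) == 0:
            continue
        r = (ev[:, None] + lag_idx[None, :]).ravel()
        c = np.broadcast_to(ci * n_lags + np.arange(n_lags), (len(ev), n_lags)).ravel()
        ok = (r >= 0) & (r < n_samples)
        rows.append(r[ok])
        cols.append(c[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones(len(rows))
    X = sp.csr_matrix(
        (data, (rows, cols)), shape=(n_samples, n_lags * len(category_order))
    )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != n_samples:
            raise ValueError("mask length must equal the sample count")
        keep = sp.diags((~mask).astype(float))
        X = keep @ X
        X.eliminate_zeros()
    return DeconvDesign(
        matrix=X.tocsr(),
        lags=lags,
        categories=tuple(category_order),
        rate=rate,
        mask=mask,
        n_events=n_events,
    )


def fit_deconvolution(
    eeg: EEGRecording,
    design: DeconvDesign,
    solver: str = "direct",
    tol: float = 1e-10,
    maxiter: int = 20000,
) -> DeconvResult:
    """Least-squares kernels per channel from the time-expanded model.

    ``solver="direct"`` (default) solves the sparse normal equations with
    one Cholesky factorization shared by all channels — exact and
    deterministic. ``solver="lsmr"`` runs the iterative sparse solver
    with atol=btol=``tol`` and an iteration cap. Categories without
    events yield NaN ("undefined") kernels; the others are returned.
    """
    X = design.matrix
    if X.shape[0] != eeg.n_samples:
        raise ValueError("design rows must match the EEG sample count")
    n_lags = design.n_lags
    n_cat = len(design.categories)
    n_ch = eeg.data.shape[0]

    Y = eeg.data.T.copy()  # samples x channels
    if design.mask is not None:
        Y[design.mask] = 0.0

    active = [ci for ci, cat in enumerate(design.categories) if design.n_events[cat] > 0]
    for cat in design.categories:
        if design.n_events[cat] == 0:
            logger.warning("category %r has no events; kernel flagged undefined", cat)
    col_sel = np.concatenate([np.arange(ci * n_lags, (ci + 1) * n_lags) for ci in active])
    Xa = X[:, col_sel]

    beta_a = np.empty((len(col_sel), n_ch))
    if solver == "direct":
        A = (Xa.T @ Xa).toarray()
        B = Xa.T @ Y
        try:
            c, low = scipy.linalg.cho_factor(A)
            beta_a = scipy.linalg.cho_solve((c, low), B)
        except np.linalg.LinAlgError:
            logger.warning("normal equations not positive definite; using lstsq")
            beta_a = np.linalg.lstsq(A, B, rcond=None)[0]
    elif solver == "lsmr":
        for ch in range(n_ch):
            beta_a[:, ch] = lsmr(Xa, Y[:, ch], atol=tol, btol=tol, maxiter=maxiter)[0]
    else:
        raise ValueError(f"unknown solver {solver!r}")

    beta = np.full((n_cat * n_lags, n_ch), np.nan)
    beta[col_sel] = beta_a
    kernels = beta.T.reshape(n_ch, n_cat, n_lags).transpose(1, 0, 2)

    resid = Y - Xa @ beta_a
    if design.mask is not None:
        resid = resid[~design.mask]
    residual_var = resid.var(axis=0)
    return DeconvResult(
        kernels=kernels,
        lags=design.lags,
        categories=design.categories,
        labels=tuple(eeg.labels),
        residual_var=residual_var,
        n_events=design.n_events,
    )


def naive_kernels(
    eeg: EEGRecording,
    trigger_samples,
    categories,
    window: tuple[float, float] = WINDOW_DECONV,
    category_order: tuple = CATEGORIES,
) -> DeconvResult:
    """Per-category epoch averages on the deconvolution lag axis.

    The uncorrected comparator: identical to the deconvolved kernels when
    events never overlap, biased when they do.
    """
    import pandas as pd

    trigger_samples = np.asarray(trigger_samples, dtype=int)
    categories = np.asarray(categories)
    md = pd.DataFrame({"category": categories})
    ep = extract_epochs(eeg, trigger_samples, window, metadata=md, alignment="saccade")
    lag_idx = np.arange(round(window[0] * eeg.rate), round(window[1] * eeg.rate) + 1)
    lags = lag_idx / eeg.rate
    n_ch = eeg.data.shape[0]
    kernels = np.full((len(category_order), n_ch, len(lags)), np.nan)
    n_events = {}
    for ci, cat in enumerate(category_order):
        idx = np.flatnonzero(ep.metadata["category"].to_numpy() == cat)
        n_events[cat] = len(idx)
        if len(idx):
            kernels[ci] = ep.data[idx].mean(axis=0)
    return DeconvResult(
        kernels=kernels,
        lags=lags,
        categories=tuple(category_order),
        labels=tuple(eeg.labels),
        residual_var=np.full(n_ch, np.nan),
        n_events=n_events,
    )
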