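"""Synthetic 32-channel EEG montage.

A standard 10-20 subset with approximate 2-D (flattened-cap) coordinates.
The layout serves two purposes: it gives the forward model a spatial
topography (posterior-weighted visual components), and it defines channel
adjacency for the cluster-enhancement statistics via Delaunay triangulation.

Coordinate convention: x positive toward the right ear, y positive toward
the nose, unit head radius.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay

# name -> (x, y), approximate equal-area projection of the 10-20 positions
_LAYOUT_32 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.43, 0.55), "Fz": (0.0, 0.51),
    "F4": (0.43, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.66, 0.28), "FC1": (-0.24, 0.26), "FC2": (0.24, 0.26),
    "FC6": (0.66, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.51, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.51, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.66, -0.28), "CP1": (-0.24, -0.26), "CP2": (0.24, -0.26),
    "CP6": (0.66, -0.28),
    "P7": (-0.81, -0.59), "P3": (-0.43, -0.55), "Pz": (0.0, -0.51),
    "P4": (0.43, -0.55), "P8": (0.81, -0.59), "P2": (0.22, -0.53),
    "PO7": (-0.57, -0.78), "PO3": (-0.28, -0.76), "PO4": (0.28, -0.76),
    "PO8": (0.57, -0.78),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

CHANNELS_32 = tuple(_LAYOUT_32)

#: channels used for headline posterior statistics (P100 / face effects)
POSTERIOR_CHANNELS = ("PO7", "PO8", "PO3", "PO4", "O1", "O2", "P7", "P8")


def channel_positions(labels=CHANNELS_32) -> np.ndarray:
    """Return the (n_channels, 2) layout coordinates for ``labels``."""
    try:
        return np.array([_LAYOUT_32[c] for c in labels], dtype=float)
    except KeyError as exc:  # pragma: no cover - defensive
        raise KeyError(f"unknown channel label {exc.args[0]!r}") from exc


def channel_adjacency(pos: np.ndarray) -> sp.csr_matrix:
    """Symmetric boolean channel-neighbor matrix from Delaunay triangulation.

    Delaunay neighbors of the 2-D layout are a standard, montage-agnostic
    adjacency choice for sensor-space cluster statistics. For fewer than
    four channels (degenerate triangulation) a chain over the x-sorted
    order is used instead.
    """
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    if n < 2:
        return sp.csr_matrix((n, n), dtype=bool)
    rows, cols = [], []
    if n < 4:
        order = np.argsort(pos[:, 0], kind="stable")
        for a, b in zip(order[:-1], order[1:]):
            rows += [a, b]
            cols += [b, a]
    else:
        tri = Delaunay(pos)
        for simplex in tri.simplices:
            for i in range(3):
                a, b = simplex[i], simplex[(i + 1) % 3]
                rows += [a, b]
                cols += [b, a]
    data = np.ones(len(rows), dtype=bool)
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n), dtype=bool)
    adj.setdiag(False)
    adj.eliminate_zeros()
    return adj


def posterior_gain(pos: np.ndarray, foci=("PO7", "PO8"), width: float = 0.45) -> np.ndarray:
    """Smooth per-channel gain peaked at posterior foci (max 1).

    Used by the forward model to give visual components a realistic
    occipito-parietal topography.
    """
    pos = np.asarray(pos, dtype=float)
    centers = channel_positions(foci)
    g = np.zeros(len(pos))
    for c in centers:
        d2 = np.sum((pos - c) ** 2, axis=1)
        g = np.maximum(g, np.exp(-d2 / (2.0 * width**2)))
    return g
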