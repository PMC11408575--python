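"""Topographic similarity primitives.

The spatial correlation between two scalp maps u, v over F electrodes is the
uncentered (cosine) correlation

    Corr(u, v) = Σᵢ uᵢ vᵢ / (‖u‖ ‖v‖),

which is polarity-sensitive: an inverted map scores −1, not +1.  This is
deliberate — classical microstate analysis rectifies polarity, which discards
exactly the information that distinguishes, say, an N2 from a P2.  An optional
``centered`` flag subtracts each map's mean across electrodes first (classical
Pearson across the electrode dimension).

The inner similarity of a time window is the mean spatial correlation over all
unordered pairs of distinct time points inside it; values near 1 indicate a
quasi-stable topography.
"""

from __future__ import annotations

import numpy as np

from .datamodel import TimeWindow

__all__ = [
    "spatial_correlation",
    "inner_similarity",
    "mean_topography",
    "window_amplitude",
]


def _prep(u: np.ndarray, centered: bool) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise ValueError("topography must be a 1-D vector")
    if centered:
        u = u - u.mean()
    return u


def spatial_correlation(u: np.ndarray, v: np.ndarray, centered: bool = False) -> float:
    """Cosine correlation between two topographies (in [-1, 1])."""
    u = _prep(u, centered)
    v = _prep(v, centered)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch {u.shape} vs {v.shape}")
    if u.size < 2:
        raise ValueError("topographies need at least 2 electrodes")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroDivisionError("spatial correlation undefined for zero-norm map")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def inner_similarity(window: np.ndarray, centered: bool = False) -> float:
    """Mean pairwise spatial correlation over the rows of ``window``.

    ``window`` is ``(n, F)`` with n ≥ 2 time points.  Computed in closed form
    from the sum of unit-normalised rows: for unit rows e₁..eₙ,
    Σ_{i≠j} eᵢ·eⱼ = ‖Σ eᵢ‖² − n.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2:
        raise ValueError("window must be a 2-D (n_time, n_chan) matrix")
    n = w.shape[0]
    if n < 2:
        raise ValueError("inner similarity needs at least 2 time points")
    if centered:
        w = w - w.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(w, axis=1)
    if np.any(norms == 0.0):
        raise ZeroDivisionError("window contains a zero-norm topography")
    e = w / norms[:, None]
    s = np.linalg.norm(e.sum(axis=0)) ** 2 - n
    return float(np.clip(s / (n * (n - 1)), -1.0, 1.0))


def mean_topography(data: np.ndarray, window: TimeWindow | slice) -> np.ndarray:
    """Centroid map: arithmetic mean of the topographies inside the window."""
    sl = window.sl if isinstance(window, TimeWindow) else window
    seg = np.asarray(data, dtype=float)[sl]
    if seg.shape[0] == 0:
        raise ValueError("empty window")
    return seg.mean(axis=0)


def window_amplitude(
    data: np.ndarray,
    window: TimeWindow | slice,
    site: str,
    channels: list[str],
) -> float:
    """Mean amplitude (µV) at one electrode site over the window."""
    try:
        ci = channels.index(site)
    except ValueError:
        raise KeyError(f"unknown site {site!r}") from None
    sl = window.sl if isinstance(window, TimeWindow) else window
    seg = np.asarray(data, dtype=float)[sl, ci]
    if seg.size == 0:
        raise ValueError("empty window")
    return float(seg.mean())
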