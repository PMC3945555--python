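"""Prewitt edge detection on the filtered spectrogram.

Wheezes appear as quasihorizontal ridges with sharp intensity transitions
along the frequency axis, so a gradient detector marks their outlines.  The
gradient magnitude defaults to the L1 combination |gx| + |gy|, the form
cheap adder-based hardware uses; L2 is available via `norm`.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .spectrogram import Spectrogram

__all__ = [
    "PREWITT_GX",
    "PREWITT_GY",
    "prewitt_magnitude",
    "prewitt_edges",
    "adaptive_edge_threshold",
]

PREWITT_GX = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=np.float64)
PREWITT_GY = PREWITT_GX.T.copy()


def _as_array(spec: Spectrogram | np.ndarray) -> np.ndarray:
    arr = spec.power if isinstance(spec, Spectrogram) else np.asarray(spec, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("edge detection requires finite input")
    return arr


def prewitt_magnitude(spec: Spectrogram | np.ndarray, norm: str = "l1") -> np.ndarray:
    """Prewitt gradient magnitude with replicate-padded borders."""
    arr = _as_array(spec)
    gx = ndimage.correlate(arr, PREWITT_GX, mode="nearest")
    gy = ndimage.correlate(arr, PREWITT_GY, mode="nearest")
    if norm == "l1":
        return np.abs(gx) + np.abs(gy)
    if norm == "l2":
        return np.hypot(gx, gy)
    raise ValueError(f"unknown gradient norm {norm!r}")


def adaptive_edge_threshold(magnitude: np.ndarray, percentile: float = 90.0) -> float:
    """Loudness-invariant threshold: a percentile of the frame's gradients."""
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(magnitude, percentile))


def prewitt_edges(
    spec: Spectrogram | np.ndarray, edge_thresh: float, norm: str = "l1"
) -> np.ndarray:
    """Binary edge mask: gradient magnitude strictly above *edge_thresh*."""
    if edge_thresh < 0:
        raise ValueError("edge threshold must be non-negative")
    return prewitt_magnitude(spec, norm=norm) > edge_thresh
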