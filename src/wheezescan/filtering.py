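"""Edge-preserving smoothing with a 7x7 bilateral filter.

Each output pixel is a normalized, weighted average of its 7x7 neighbourhood,
where the weight is the product of a spatial Gaussian (closeness in the image
plane) and a photometric Gaussian (closeness in intensity).  Strong spectral
ridges — wheezes sit well above the background in dB — therefore survive
while background noise is smoothed.

A second mode replaces the photometric exponential with a quantized look-up
table (fixed depth, fixed coefficient precision), emulating hardware that
stores filter coefficients in LUTs instead of evaluating exp().  The LUT
introduces a bounded perturbation per coefficient, which is what the
float-vs-quantized discordance report downstream measures.

Borders are handled by edge replication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .spectrogram import Spectrogram

__all__ = [
    "BilateralParams",
    "PhotometricLut",
    "bilateral_filter",
    "bilateral_filter_quantized",
    "build_photometric_lut",
]


@dataclass
class BilateralParams:
    """Bilateral filter configuration.

    radius 3 gives the 7x7 mask.  sigma_d is the spatial width in pixels;
    sigma_r the photometric width in dB.  Defaults: sigma_d=1.5 px so the
    full 7x7 support carries meaningful weight, sigma_r=6 dB so ridges more
    than ~15 dB above background are treated as edges and preserved.
    """

    radius: int = 3
    sigma_d: float = 1.5
    sigma_r: float = 6.0
    mode: str = "float"  # "float" | "quantized"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.sigma_d <= 0 or self.sigma_r <= 0:
            raise ValueError("sigma_d and sigma_r must be positive")
        if self.mode not in ("float", "quantized"):
            raise ValueError(f"unknown bilateral mode {self.mode!r}")


@dataclass
class PhotometricLut:
    """Quantized photometric weights over |intensity difference| in [0, delta_max].

    entries[i] approximates exp(-delta_i^2 / (2 sigma_r^2)) rounded to an
    integer multiple of `step`; lookups snap |delta| to the nearest grid
    point (differences beyond delta_max clamp to the last entry).
    """

    entries: np.ndarray
    depth: int
    step: float
    delta_max: float
    sigma_r: float

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.float64)
        if self.depth < 2:
            raise ValueError("LUT depth must be >= 2")
        if self.step <= 0:
            raise ValueError("LUT step must be positive")
        if len(self.entries) != self.depth:
            raise ValueError("entry count must equal depth")

    @property
    def grid_spacing(self) -> float:
        return self.delta_max / (self.depth - 1)

    def weight(self, delta: np.ndarray) -> np.ndarray:
        """Quantized weight for (signed) intensity differences."""
        idx = np.rint(np.abs(np.asarray(delta)) / self.grid_spacing).astype(np.int64)
        idx = np.clip(idx, 0, self.depth - 1)
        return self.entries[idx]


def build_photometric_lut(
    sigma_r: float,
    depth: int = 8192,
    step: float = 0.01,
    delta_max: float = 80.0,
) -> PhotometricLut:
    """Tabulate exp(-d^2/(2 sigma_r^2)) on a uniform grid, rounded to `step`."""
    if depth < 2:
        raise ValueError("LUT depth must be >= 2")
    if step <= 0:
        raise ValueError("LUT step must be positive")
    if sigma_r <= 0:
        raise ValueError("sigma_r must be positive")
    if delta_max <= 0:
        raise ValueError("delta_max must be positive")
    grid = np.linspace(0.0, delta_max, depth)
    exact = np.exp(-(grid**2) / (2.0 * sigma_r**2))
    entries = np.round(exact / step) * step
    return PhotometricLut(
        entries=entries, depth=depth, step=step, delta_max=delta_max, sigma_r=sigma_r
    )


def _spatial_weights(radius: int, sigma_d: float) -> np.ndarray:
    """(2r+1)x(2r+1) Gaussian closeness weights."""
    d = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(d, d, indexing="ij")
    return np.exp(-(dr**2 + dc**2) / (2.0 * sigma_d**2))


def _bilateral_core(
    arr: np.ndarray,
    radius: int,
    sigma_d: float,
    range_weight: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """Shared float/quantized implementation: normalized weighted average
    over the (2r+1)^2 neighbourhood with replicate-padded borders."""
    if not np.all(np.isfinite(arr)):
        raise ValueError("bilateral filter requires finite input")
    rows, cols = arr.shape
    wd = _spatial_weights(radius, sigma_d)
    padded = np.pad(arr, radius, mode="edge")
    num = np.zeros_like(arr)
    den = np.zeros_like(arr)
    for i in range(2 * radius + 1):
        for j in range(2 * radius + 1):
            shifted = padded[i : i + rows, j : j + cols]
            w = wd[i, j] * range_weight(shifted - arr)
            num += w * shifted
            den += w
    return num / den


def bilateral_filter(spec: Spectrogram, params: BilateralParams) -> Spectrogram:
    """Float-exact 7x7 bilateral filter of a spectrogram."""
    inv = 1.0 / (2.0 * params.sigma_r**2)
    out = _bilateral_core(
        spec.power, params.radius, params.sigma_d, lambda d: np.exp(-(d**2) * inv)
    )
    return spec.with_power(out)


def bilateral_filter_quantized(
    spec: Spectrogram, params: BilateralParams, lut: PhotometricLut | None = None
) -> Spectrogram:
    """Bilateral filter with photometric weights drawn from a quantized LUT."""
    if lut is None:
        lut = build_photometric_lut(params.sigma_r)
    out = _bilateral_core(spec.power, params.radius, params.sigma_d, lut.weight)
    return spec.with_power(out)
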