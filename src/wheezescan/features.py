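"""Shape features of detected spectrogram objects.

Four per-object parameters describe a wheeze episode's geometry:

- ``p_cy`` — centroid frequency (Hz): mean pixel row times the bin width.
- ``p_t``  — duration (ms): bounding-box width times the column period.
- ``p_s``  — slope (Hz/s): least-squares slope of per-column centroid
  frequency against time; a horizontal ridge has slope ~0.
- ``p_ar`` — area ratio: object pixels over bounding-box pixels, in (0, 1].

A frame with no surviving object carries no feature vector and is classified
"normal" without invoking the SVM; with several objects the largest-area one
represents the frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import RegionObject

__all__ = ["FEATURE_NAMES", "FeatureVector", "extract_features", "frame_feature_vector"]

FEATURE_NAMES = ("p_cy", "p_t", "p_s", "p_ar")

_ALIASES = {
    "pcy": "p_cy",
    "pt": "p_t",
    "ps": "p_s",
    "par": "p_ar",
    "p_cy": "p_cy",
    "p_t": "p_t",
    "p_s": "p_s",
    "p_ar": "p_ar",
}


def canonical_feature_names(names) -> tuple[str, ...]:
    """Normalize feature-set spellings ('pt' / 'P_T' / 'p_t' all accepted)."""
    out = []
    for name in names:
        key = name.strip().lower().replace("-", "_")
        if key not in _ALIASES:
            raise ValueError(f"unknown feature {name!r}; choose from {FEATURE_NAMES}")
        out.append(_ALIASES[key])
    return tuple(out)


@dataclass(frozen=True)
class FeatureVector:
    p_cy: float
    p_t: float
    p_s: float
    p_ar: float

    def __post_init__(self) -> None:
        vals = (self.p_cy, self.p_t, self.p_s, self.p_ar)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("feature vector contains non-finite values")
        if self.p_t < 0 or self.p_cy < 0:
            raise ValueError("duration and centroid frequency must be non-negative")
        if not 0.0 <= self.p_ar <= 1.0:
            raise ValueError("area ratio must lie in [0, 1]")

    def as_array(self, feature_set=FEATURE_NAMES) -> np.ndarray:
        names = canonical_feature_names(feature_set)
        return np.array([getattr(self, name) for name in names], dtype=np.float64)


def extract_features(
    obj: RegionObject, bin_hz: float, col_sec: float
) -> FeatureVector:
    """Compute (p_cy, p_t, p_s, p_ar) for one region."""
    r0, r1, c0, c1 = obj.bbox
    p_cy = obj.centroid_hz(bin_hz)
    p_t = obj.duration_ms(col_sec)
    p_ar = obj.area / ((r1 - r0 + 1) * (c1 - c0 + 1))

    cols = obj.pixels[:, 1]
    unique_cols = np.unique(cols)
    if len(unique_cols) < 2:
        p_s = 0.0
    else:
        # per-column centroid frequency against column time
        mean_rows = np.array(
            [obj.pixels[cols == c, 0].mean() for c in unique_cols], dtype=np.float64
        )
        times = unique_cols * col_sec
        freqs = mean_rows * bin_hz
        p_s = float(np.polyfit(times, freqs, 1)[0])
    return FeatureVector(p_cy=p_cy, p_t=p_t, p_s=p_s, p_ar=p_ar)


def frame_feature_vector(
    objects: list[RegionObject],
    bin_hz: float,
    col_sec: float,
    power_db: np.ndarray | None = None,
    strategy: str = "power",
) -> FeatureVector | None:
    """Feature vector of the frame's dominant object, or None for an empty frame.

    With strategy "power" (and the dB spectrogram supplied) the dominant
    object is the one with the greatest integrated linear power — the
    fundamental of a harmonic wheeze always beats its own harmonics and
    diffuse noise blobs, whereas raw pixel *area* can be won by a harmonic
    ridge sitting on a quieter part of the spectrum.  Strategy "area" (or a
    missing spectrogram) falls back to the largest-area object.
    """
    if not objects:
        return None
    if strategy not in ("power", "area"):
        raise ValueError(f"unknown aggregation strategy {strategy!r}")
    if strategy == "power" and power_db is not None:
        lin = 10.0 ** (np.asarray(power_db, float) / 10.0)
        best = max(
            objects, key=lambda o: lin[o.pixels[:, 0], o.pixels[:, 1]].sum()
        )
    else:
        best = max(objects, key=lambda o: o.area)
    return extract_features(best, bin_hz, col_sec)
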