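"""Audio ingestion and framing.

The detector consumes mono respiratory-sound recordings and analyses them in
consecutive, non-overlapping 2-second units.  At the nominal sampling rate of
4410 Hz one unit is exactly 8820 samples; that frame is the atom every
downstream stage (spectrogram, segmentation, classification) operates on.
Recordings at other rates are accepted only through explicit polyphase
resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "NOMINAL_RATE",
    "FRAME_LEN",
    "SampleBuffer",
    "AudioFrame",
    "load_audio",
    "load_raw_pcm",
    "frame_signal",
]

log = logging.getLogger(__name__)

#: Nominal sampling rate in Hz (8820 samples per 2-second unit).
NOMINAL_RATE = 4410
#: Samples per 2-second processing unit.
FRAME_LEN = 8820


@dataclass
class SampleBuffer:
    """A mono signal with its sampling rate.

    Amplitudes are dimensionless floats nominally in [-1, 1]; integer PCM is
    rescaled on load.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("sample buffer contains non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class AudioFrame:
    """One 2-second unit of exactly 8820 samples — the unit of classification."""

    samples: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if len(self.samples) != FRAME_LEN:
            raise ValueError(
                f"frame must have {FRAME_LEN} samples, got {len(self.samples)}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("frame contains non-finite values")


def _pcm_to_float(data: np.ndarray) -> np.ndarray:
    """Rescale integer PCM to floats in [-1, 1]; pass floats through."""
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    if data.dtype == np.uint8:  # WAV 8-bit is unsigned
        return (data.astype(np.float64) - 128.0) / 128.0
    info = np.iinfo(data.dtype)
    return data.astype(np.float64) / float(-info.min)


def load_audio(path: str | Path, target_rate: int = NOMINAL_RATE) -> SampleBuffer:
    """Read a WAV file, mix to mono, normalize, and resample to *target_rate*.

    Raises OSError for unreadable/corrupt files and ValueError for
    zero-length audio.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises assorted types for bad files
        raise OSError(f"could not decode audio file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"audio file {path} contains no samples")
    if data.ndim == 2:  # mix multichannel down to mono by averaging
        data = data.mean(axis=1)
    x = _pcm_to_float(np.asarray(data))
    if rate != target_rate:
        frac = Fraction(target_rate, rate)
        x = resample_poly(x, frac.numerator, frac.denominator)
        log.info("resampled %s from %d Hz to %d Hz", path.name, rate, target_rate)
    return SampleBuffer(samples=x, rate=target_rate)


def load_raw_pcm(
    path: str | Path,
    rate: int,
    dtype: str = "int16",
    target_rate: int = NOMINAL_RATE,
) -> SampleBuffer:
    """Read headerless PCM with an explicit sampling *rate* and sample *dtype*."""
    data = np.fromfile(Path(path), dtype=np.dtype(dtype))
    if data.size == 0:
        raise ValueError(f"raw PCM file {path} contains no samples")
    x = _pcm_to_float(data)
    if rate != target_rate:
        frac = Fraction(target_rate, rate)
        x = resample_poly(x, frac.numerator, frac.denominator)
    return SampleBuffer(samples=x, rate=target_rate)


def frame_signal(buf: SampleBuffer) -> list[AudioFrame]:
    """Cut a buffer into consecutive non-overlapping 8820-sample frames.

    A trailing remainder shorter than one frame is discarded (and logged).
    Buffers shorter than one frame yield an empty list.
    """
    if buf.rate != NOMINAL_RATE:
        raise ValueError(
            f"frame_signal expects {NOMINAL_RATE} Hz input, got {buf.rate} Hz; "
            "resample via load_audio(..., target_rate=4410)"
        )
    n = len(buf.samples) // FRAME_LEN
    remainder = len(buf.samples) - n * FRAME_LEN
    if n == 0:
        log.warning(
            "buffer of %d samples is shorter than one %d-sample frame",
            len(buf.samples),
            FRAME_LEN,
        )
        return []
    if remainder:
        log.info("discarding trailing %d samples (< one frame)", remainder)
    return [
        AudioFrame(samples=buf.samples[i * FRAME_LEN : (i + 1) * FRAME_LEN], index=i)
        for i in range(n)
    ]
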