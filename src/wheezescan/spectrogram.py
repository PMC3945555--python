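"""Power spectrogram of one 2-second frame.

STFT with a 256-point Hanning window and 50% overlap (hop 128).  An
8820-sample frame yields floor((8820-256)/128)+1 = 67 full windows; the
trailing 116 samples never fill a window and are dropped — no zero padding.
The one-sided spectrum keeps bins 0..128, so the image is 129 rows x 67
columns with calibration 4410/256 ~= 17.2266 Hz/bin and 128/4410 ~= 29.025
ms/column.

Power is reported in dB (10*log10 |X[k]|^2) with a configurable floor so that
log-of-zero stays finite and the bilateral filter's photometric width can be
stated in dB independently of recording loudness.  Linear power is available
for energy checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_audio import FRAME_LEN, NOMINAL_RATE, AudioFrame

__all__ = [
    "N_FFT",
    "HOP",
    "N_BINS",
    "N_COLS",
    "BIN_HZ",
    "COL_SEC",
    "Spectrogram",
    "hann_window",
    "compute_spectrogram",
]

N_FFT = 256
HOP = 128
N_BINS = N_FFT // 2 + 1  # one-sided spectrum, 129 bins
N_COLS = (FRAME_LEN - N_FFT) // HOP + 1  # 67 columns per 2-s frame
BIN_HZ = NOMINAL_RATE / N_FFT  # ~17.2266 Hz per frequency bin
COL_SEC = HOP / NOMINAL_RATE  # ~29.025 ms per time column


@dataclass
class Spectrogram:
    """Time-frequency image: rows are frequency bins, columns are time windows."""

    power: np.ndarray  # (n_bins, n_cols)
    bin_hz: float = BIN_HZ
    col_sec: float = COL_SEC
    scale: str = "db"  # "db" | "linear"

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 2:
            raise ValueError("spectrogram power must be a 2-D matrix")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("spectrogram contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.power.shape

    def with_power(self, power: np.ndarray) -> "Spectrogram":
        """Same axis calibration, new pixel values."""
        return Spectrogram(
            power=power, bin_hz=self.bin_hz, col_sec=self.col_sec, scale=self.scale
        )


def hann_window(n: int) -> np.ndarray:
    """Symmetric Hanning window w[k] = 0.5*(1 - cos(2*pi*k/(n-1)))."""
    if n < 2:
        raise ValueError(f"window length must be >= 2, got {n}")
    k = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (n - 1)))


def compute_spectrogram(
    frame: AudioFrame, floor_db: float = -80.0, scale: str = "db"
) -> Spectrogram:
    """STFT power spectrogram of one frame.

    Parameters
    ----------
    frame : AudioFrame
        The 8820-sample unit.
    floor_db : float
        Lower clamp for dB values (silent bins land exactly here).
    scale : {"db", "linear"}
        dB for the detection pipeline, linear for energy bookkeeping.
    """
    x = frame.samples
    if len(x) != FRAME_LEN:
        raise ValueError(f"expected a {FRAME_LEN}-sample frame")
    if scale not in ("db", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    w = hann_window(N_FFT)
    windows = np.lib.stride_tricks.sliding_window_view(x, N_FFT)[::HOP][:N_COLS]
    spectra = np.fft.rfft(windows * w, axis=1)
    power = np.abs(spectra) ** 2  # (n_cols, n_bins)
    power = power.T  # rows = frequency bins
    if scale == "linear":
        return Spectrogram(power=power, scale="linear")
    floor_lin = 10.0 ** (floor_db / 10.0)
    db = 10.0 * np.log10(np.maximum(power, floor_lin))
    return Spectrogram(power=db, scale="db")
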