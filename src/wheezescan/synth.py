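"""Seeded synthetic respiratory-sound generator.

Provides labeled 2-second frames with the structure the detection pipeline
assumes, standing in for clinical recordings that cannot be redistributed.

A frame's background is low-pass-filtered Gaussian noise shaped by a slow
raised-sine respiratory envelope.  A wheeze adds a harmonic tone — sampled
fundamental, harmonics at halving amplitude, optional linear frequency glide,
random onset — scaled so the tone's RMS sits a configured number of dB above
the background noise's RMS within the wheeze band.  Every frame is a pure
function of (config, wheeze flag, per-frame seed), so datasets regenerate
bit-identically from their manifest.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfilt

from .io_audio import FRAME_LEN, NOMINAL_RATE, AudioFrame

__all__ = ["SynthConfig", "WheezeTruth", "generate_frame", "generate_dataset",
           "regenerate_from_manifest", "write_dataset"]

_NYQUIST = NOMINAL_RATE / 2.0
_BACKGROUND_RMS = 0.05
_RAMP_S = 0.010  # cosine on/offset ramp, avoids clicks


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for synthetic frames.

    Defaults model typical expiratory wheezes: fundamental 150-600 Hz with two
    harmonics (keeps the highest component below Nyquist even at maximum
    glide), 300-1200 ms duration, near-horizontal glides (+-50 Hz/s), 15 dB
    in-band SNR, and a 0.25 Hz breathing envelope.
    """

    n_frames: int = 200
    wheeze_fraction: float = 0.5
    fundamental_hz: tuple[float, float] = (150.0, 600.0)
    n_harmonics: int = 2
    duration_ms: tuple[float, float] = (300.0, 1200.0)
    glide_hz_per_s: tuple[float, float] = (-50.0, 50.0)
    snr_db: float = 15.0
    breath_rate_hz: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        f_lo, f_hi = self.fundamental_hz
        d_lo, d_hi = self.duration_ms
        g = max(abs(self.glide_hz_per_s[0]), abs(self.glide_hz_per_s[1]))
        if not (100.0 <= f_lo <= f_hi <= 1000.0):
            raise ValueError("fundamental range must lie within [100, 1000] Hz")
        if not (250.0 <= d_lo <= d_hi <= 2000.0):
            raise ValueError("duration range must lie within [250, 2000] ms")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")
        worst = (f_hi + g * d_hi / 1000.0) * (self.n_harmonics + 1)
        if worst >= _NYQUIST:
            raise ValueError(
                f"highest harmonic can reach {worst:.0f} Hz, above Nyquist "
                f"{_NYQUIST:.0f} Hz; reduce fundamental range, glide, or harmonics"
            )
        if not 0.0 <= self.wheeze_fraction <= 1.0:
            raise ValueError("wheeze_fraction must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.breath_rate_hz <= 0:
            raise ValueError("breath rate must be positive")


@dataclass(frozen=True)
class WheezeTruth:
    """Ground truth of one injected wheeze episode."""

    f0_hz: float  # fundamental at episode onset
    glide_hz_per_s: float
    onset_s: float
    duration_ms: float

    @property
    def center_hz(self) -> float:
        """Fundamental frequency at the episode's temporal midpoint."""
        return self.f0_hz + self.glide_hz_per_s * self.duration_ms / 2000.0


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(FRAME_LEN) / NOMINAL_RATE
    noise = rng.standard_normal(FRAME_LEN)
    sos = butter(4, 1200.0, btype="low", fs=NOMINAL_RATE, output="sos")
    noise = sosfilt(sos, noise)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    envelope = 0.6 + 0.4 * np.sin(2.0 * np.pi * cfg.breath_rate_hz * t + phase)
    bg = noise * envelope
    return bg * (_BACKGROUND_RMS / np.sqrt(np.mean(bg**2)))


def _band_rms(x: np.ndarray, lo_hz: float, hi_hz: float) -> float:
    """RMS of x restricted (via FFT masking) to the [lo, hi] Hz band."""
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / NOMINAL_RATE)
    spectrum[(freqs < lo_hz) | (freqs > hi_hz)] = 0.0
    banded = np.fft.irfft(spectrum, n=len(x))
    return float(np.sqrt(np.mean(banded**2)))


def generate_frame(
    cfg: SynthConfig, wheeze: bool, rng: np.random.Generator
) -> tuple[AudioFrame, str, WheezeTruth | None]:
    """One labeled 2-second frame; deterministic given cfg, flag, and rng state."""
    cfg.validate()
    bg = _background(cfg, rng)
    if not wheeze:
        return AudioFrame(samples=np.clip(bg, -1.0, 1.0)), "normal", None

    f0 = rng.uniform(*cfg.fundamental_hz)
    duration_ms = rng.uniform(*cfg.duration_ms)
    dur_s = duration_ms / 1000.0
    glide = rng.uniform(*cfg.glide_hz_per_s)
    onset = rng.uniform(0.0, 2.0 - dur_s)

    t = np.arange(FRAME_LEN) / NOMINAL_RATE
    idx = (t >= onset) & (t < onset + dur_s)
    tau = t[idx] - onset
    # instantaneous fundamental f0 + glide*tau -> phase integral
    base_phase = 2.0 * np.pi * (f0 * tau + 0.5 * glide * tau**2)
    tone = np.zeros_like(tau)
    for h in range(1, cfg.n_harmonics + 2):
        amp = 0.5 ** (h - 1)
        tone += amp * np.cos(h * base_phase + rng.uniform(0.0, 2.0 * np.pi))
    ramp_n = max(1, min(int(_RAMP_S * NOMINAL_RATE), len(tau) // 4))
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    tone[:ramp_n] *= ramp
    tone[-ramp_n:] *= ramp[::-1]

    f_end = f0 + glide * dur_s
    band_lo = max(20.0, min(f0, f_end) - 30.0)
    band_hi = min(_NYQUIST - 1.0, max(f0, f_end) * (cfg.n_harmonics + 1) + 30.0)
    noise_rms = _band_rms(bg, band_lo, band_hi)
    tone_rms = float(np.sqrt(np.mean(tone**2)))
    scale = noise_rms * 10.0 ** (cfg.snr_db / 20.0) / tone_rms

    x = bg.copy()
    x[idx] += scale * tone
    peak = np.max(np.abs(x))
    if peak > 1.0:  # uniform rescale preserves the SNR
        x /= peak * 1.01
    truth = WheezeTruth(
        f0_hz=f0, glide_hz_per_s=glide, onset_s=onset, duration_ms=duration_ms
    )
    return AudioFrame(samples=x), "wheeze", truth


def generate_dataset(
    cfg: SynthConfig,
) -> tuple[list[AudioFrame], list[str], list[WheezeTruth | None], dict]:
    """n_frames labeled frames at the configured wheeze fraction.

    The wheeze count is exactly round(n_frames * wheeze_fraction); positions
    and per-frame seeds derive from cfg.seed.  The manifest records both, so
    `regenerate_from_manifest` reproduces the dataset bit-identically.
    """
    cfg.validate()
    master = np.random.default_rng(cfg.seed)
    n_wheeze = round(cfg.n_frames * cfg.wheeze_fraction)
    flags = np.zeros(cfg.n_frames, dtype=bool)
    flags[master.permutation(cfg.n_frames)[:n_wheeze]] = True
    frame_seeds = master.integers(0, 2**31 - 1, size=cfg.n_frames)

    frames, labels, truths, entries = [], [], [], []
    for i in range(cfg.n_frames):
        frame, label, truth = generate_frame(
            cfg, bool(flags[i]), np.random.default_rng(int(frame_seeds[i]))
        )
        frame.index = i
        frames.append(frame)
        labels.append(label)
        truths.append(truth)
        entries.append(
            {
                "index": i,
                "seed": int(frame_seeds[i]),
                "label": label,
                "truth": None if truth is None else asdict(truth),
            }
        )
    manifest = {"config": asdict(cfg), "frames": entries}
    return frames, labels, truths, manifest


def regenerate_from_manifest(
    manifest: dict,
) -> tuple[list[AudioFrame], list[str], list[WheezeTruth | None]]:
    """Rebuild a dataset from its manifest (bit-identical to the original)."""
    cfg_dict = dict(manifest["config"])
    for key in ("fundamental_hz", "duration_ms", "glide_hz_per_s"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = SynthConfig(**cfg_dict)
    frames, labels, truths = [], [], []
    for entry in manifest["frames"]:
        frame, label, truth = generate_frame(
            cfg, entry["label"] == "wheeze", np.random.default_rng(entry["seed"])
        )
        frame.index = entry["index"]
        frames.append(frame)
        labels.append(label)
        truths.append(truth)
    return frames, labels, truths


def write_dataset(out_dir: str | Path, cfg: SynthConfig) -> Path:
    """Emit WAV files plus labels.csv and manifest.json under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames, labels, _, manifest = generate_dataset(cfg)
    rows = []
    for frame, label in zip(frames, labels):
        name = f"frame_{frame.index:04d}.wav"
        pcm = np.clip(frame.samples, -1.0, 1.0)
        wavfile.write(out_dir / name, NOMINAL_RATE, (pcm * 32767).astype(np.int16))
        rows.append((name, label))
    with open(out_dir / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        writer.writerows(rows)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
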