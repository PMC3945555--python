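"""End-to-end detection pipeline and the float-vs-quantized comparison.

Per frame: spectrogram -> bilateral filter -> Prewitt edge mask ->
multithreshold segmentation with CORSA sifting -> shape features of the
largest surviving object -> RBF-SVM prediction.  Frames with no surviving
object bypass the SVM and are labeled "normal".

`compare_quantized` runs the identical pipeline twice — exact photometric
weights vs the quantized LUT — and tabulates label discordance, the software
counterpart of checking a fixed-point hardware port against its floating-point
reference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .classify import DEFAULT_FEATURE_SET, GridSpec, SvmModel, grid_search, train_svm
from .edges import adaptive_edge_threshold, prewitt_edges, prewitt_magnitude
from .features import FeatureVector, frame_feature_vector
from .filtering import (
    BilateralParams,
    PhotometricLut,
    bilateral_filter,
    bilateral_filter_quantized,
    build_photometric_lut,
)
from .io_audio import AudioFrame
from .metrics import ConfusionCounts, confusion, performance, sensitivity, specificity
from .segmentation import CorsaRules, RegionObject, multithreshold_segment
from .spectrogram import Spectrogram, compute_spectrogram

__all__ = [
    "PipelineConfig",
    "FrameResult",
    "DetectionRecord",
    "DiscordanceReport",
    "process_frame",
    "extract_frame_features",
    "detect_frames",
    "fit_detector",
    "evaluate_frames",
    "compare_quantized",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage's tunable parameters, overridable from YAML/JSON."""

    floor_db: float = -80.0
    bilateral_sigma_d: float = 1.5
    bilateral_sigma_r: float = 6.0
    bilateral_mode: str = "float"  # "float" | "quantized"
    lut_depth: int = 8192
    lut_step: float = 0.01
    lut_delta_max: float | None = None  # default: |floor_db|
    edge_percentile: float = 90.0
    edge_norm: str = "l1"
    seg_levels: tuple[float, ...] = (24.0, 21.0, 18.0, 15.0)
    seg_threshold_mode: str = "offset_db"  # "offset_db" | "percentile"
    background_quantile: float = 25.0
    overlap_frac: float = 0.3
    se_size: int = 3
    connectivity: int = 8
    min_freq_hz: float = 100.0
    min_duration_ms: float = 100.0
    feature_set: tuple[str, ...] = DEFAULT_FEATURE_SET
    aggregation: str = "power"  # dominant-object vote: "power" | "area"

    def bilateral_params(self, mode: str | None = None) -> BilateralParams:
        return BilateralParams(
            sigma_d=self.bilateral_sigma_d,
            sigma_r=self.bilateral_sigma_r,
            mode=mode or self.bilateral_mode,
        )

    def lut(self) -> PhotometricLut:
        delta_max = self.lut_delta_max
        if delta_max is None:
            delta_max = abs(self.floor_db)
        return build_photometric_lut(
            self.bilateral_sigma_r,
            depth=self.lut_depth,
            step=self.lut_step,
            delta_max=delta_max,
        )

    def corsa_rules(self) -> CorsaRules:
        return CorsaRules(
            min_freq_hz=self.min_freq_hz, min_duration_ms=self.min_duration_ms
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seg_levels"] = list(self.seg_levels)
        d["feature_set"] = list(self.feature_set)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "seg_levels" in d:
            d["seg_levels"] = tuple(d["seg_levels"])
        if "feature_set" in d:
            d["feature_set"] = tuple(d["feature_set"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data or {})


@dataclass
class FrameResult:
    """Everything one frame's trip through the pipeline produced."""

    index: int
    spectrogram: Spectrogram
    filtered: Spectrogram
    edge_mask: np.ndarray
    objects: list[RegionObject]
    feature: FeatureVector | None
    stage_counts: dict


@dataclass
class DetectionRecord:
    index: int
    label: str
    decision_value: float | None
    feature: FeatureVector | None


@dataclass
class DiscordanceReport:
    """Label disagreement between float and LUT-quantized pipelines."""

    n_total: int
    float_wheeze_quant_normal: int
    float_normal_quant_wheeze: int

    @property
    def n_discordant(self) -> int:
        return self.float_wheeze_quant_normal + self.float_normal_quant_wheeze

    @property
    def error_rate(self) -> float:
        """Discordant fraction, reported at 4 decimals."""
        return round(self.n_discordant / self.n_total, 4)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "float_wheeze_quant_normal": self.float_wheeze_quant_normal,
            "float_normal_quant_wheeze": self.float_normal_quant_wheeze,
            "n_discordant": self.n_discordant,
            "error_rate": self.error_rate,
        }


def process_frame(
    frame: AudioFrame,
    config: PipelineConfig = PipelineConfig(),
    lut: PhotometricLut | None = None,
) -> FrameResult:
    """Run one frame through spectrogram, filtering, edges, and segmentation."""
    spec = compute_spectrogram(frame, floor_db=config.floor_db)
    if config.bilateral_mode == "quantized":
        filtered = bilateral_filter_quantized(
            spec, config.bilateral_params(), lut if lut is not None else config.lut()
        )
    else:
        filtered = bilateral_filter(spec, config.bilateral_params())
    magnitude = prewitt_magnitude(filtered, norm=config.edge_norm)
    thresh = adaptive_edge_threshold(magnitude, config.edge_percentile)
    edge_mask = magnitude > thresh
    objects = multithreshold_segment(
        filtered,
        edge_mask,
        levels=config.seg_levels,
        threshold_mode=config.seg_threshold_mode,
        background_quantile=config.background_quantile,
        rules=config.corsa_rules(),
        overlap_frac=config.overlap_frac,
        se_size=config.se_size,
        connectivity=config.connectivity,
    )
    feature = frame_feature_vector(
        objects,
        filtered.bin_hz,
        filtered.col_sec,
        power_db=filtered.power,
        strategy=config.aggregation,
    )
    counts = {"edge_pixels": int(edge_mask.sum()), "objects": len(objects)}
    log.debug("frame %d: %s", frame.index, counts)
    return FrameResult(
        index=frame.index,
        spectrogram=spec,
        filtered=filtered,
        edge_mask=edge_mask,
        objects=objects,
        feature=feature,
        stage_counts=counts,
    )


def extract_frame_features(
    frames: list[AudioFrame],
    config: PipelineConfig = PipelineConfig(),
) -> list[FeatureVector | None]:
    """Per-frame feature vectors (None where no object survived sifting)."""
    lut = config.lut() if config.bilateral_mode == "quantized" else None
    return [process_frame(f, config, lut=lut).feature for f in frames]


def detect_frames(
    frames: list[AudioFrame],
    model: SvmModel,
    config: PipelineConfig = PipelineConfig(),
) -> list[DetectionRecord]:
    """Classify each frame; featureless frames are 'normal' without the SVM."""
    records = []
    lut = config.lut() if config.bilateral_mode == "quantized" else None
    for frame in frames:
        fv = process_frame(frame, config, lut=lut).feature
        if fv is None:
            records.append(DetectionRecord(frame.index, "normal", None, None))
        else:
            label, dv = model.predict(fv)
            records.append(DetectionRecord(frame.index, label, dv, fv))
    return records


def fit_detector(
    frames: list[AudioFrame],
    labels: list[str],
    config: PipelineConfig = PipelineConfig(),
    grid: GridSpec | None = None,
    c: float = 10.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> SvmModel:
    """Extract features and train the SVM (grid-searched when *grid* given).

    Frames whose pipeline produced no object carry no feature vector and are
    excluded from SVM training — at detection time they are 'normal' anyway.
    """
    feats = extract_frame_features(frames, config)
    X = [fv for fv in feats if fv is not None]
    y = [lab for fv, lab in zip(feats, labels) if fv is not None]
    dropped = len(feats) - len(X)
    if dropped:
        log.info("excluding %d featureless frames from training", dropped)
    if grid is not None:
        c, sigma, _ = grid_search(X, y, grid, seed=seed, feature_set=config.feature_set)
    return train_svm(X, y, c=c, sigma=sigma, feature_set=config.feature_set)


def evaluate_frames(
    frames: list[AudioFrame],
    labels: list[str],
    model: SvmModel,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Confusion counts plus SE/SP/PER for labeled frames."""
    records = detect_frames(frames, model, config)
    counts = confusion(labels, [r.label for r in records])
    return {
        "counts": counts,
        "sensitivity": sensitivity(counts),
        "specificity": specificity(counts),
        "performance": performance(counts),
    }


def compare_quantized(
    frames: list[AudioFrame],
    model: SvmModel,
    config: PipelineConfig = PipelineConfig(),
) -> DiscordanceReport:
    """Label discordance between the float and LUT-quantized pipelines."""
    if not frames:
        raise ValueError("at least one frame is required")
    float_cfg = replace(config, bilateral_mode="float")
    quant_cfg = replace(config, bilateral_mode="quantized")
    float_labels = [r.label for r in detect_frames(frames, model, float_cfg)]
    quant_labels = [r.label for r in detect_frames(frames, model, quant_cfg)]
    fw_qn = sum(
        1 for f, q in zip(float_labels, quant_labels) if f == "wheeze" and q == "normal"
    )
    fn_qw = sum(
        1 for f, q in zip(float_labels, quant_labels) if f == "normal" and q == "wheeze"
    )
    return DiscordanceReport(
        n_total=len(frames),
        float_wheeze_quant_normal=fw_qn,
        float_normal_quant_wheeze=fn_qw,
    )
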