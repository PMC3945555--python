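# Methods

## Processing model

`wheezescan` treats wheeze detection as an image-analysis problem on the
short-time power spectrogram of 2-second sound units. The assumptions are:

- a wheeze is a *continuous* tonal event — a fundamental plus harmonics —
  that shows up as a quasihorizontal ridge standing well above the local
  background, lasting more than 100 ms at a dominant frequency above 100 Hz
  (the CORSA criteria);
- background breath sound is broadband, strongly low-passed noise whose
  level varies slowly with the respiratory cycle;
- per-frame processing is sufficient: no state is carried between 2-second
  units, which keeps latency and memory bounded.

### Frame geometry

The nominal sampling rate is 4410 Hz, so one unit is 8820 samples. The STFT
uses a 256-point symmetric Hanning window with hop 128 (50% overlap), giving
67 full windows per unit (the trailing 116 samples never fill a window and
are dropped; there is no zero padding). The one-sided spectrum keeps bins
0–128. Calibration: 4410/256 ≈ 17.227 Hz per bin, 128/4410 ≈ 29.025 ms per
column. Power is stored as 10·log10|X[k]|², clamped at a floor (default
−80 dB) so silent bins stay finite. dB rather than linear power makes the
bilateral filter's photometric width loudness-independent; no per-frame
normalization is applied, so SNR information survives into segmentation.

## Stage parameters

| parameter | default | units | why |
|---|---|---|---|
| `floor_db` | −80 | dB | below any signal of interest; defines LUT input range |
| `bilateral_sigma_d` | 1.5 | px | 7×7 support carries meaningful weight at radius 3 |
| `bilateral_sigma_r` | 6 | dB | ridges ≥ ~15 dB above background are treated as edges |
| `lut_depth` / `lut_step` | 8192 / 0.01 | — | fixed-point table emulation |
| `edge_percentile` | 90 | % | loudness-invariant gradient threshold |
| `seg_levels` | 24, 21, 18, 15 | dB | offsets above per-bin background (see below) |
| `background_quantile` | 25 | % | per-row background estimate robust to ridges ≤ 75% of frame |
| `overlap_frac` | 0.3 | — | fraction of object pixels that must lie on (dilated) edges |
| `se_size` | 3 | px | morphological element size |
| `min_freq_hz` / `min_duration_ms` | 100 / 100 | Hz / ms | CORSA criteria |
| `feature_set` | (p_t, p_s) | — | smallest well-performing subset |

The quantized bilateral mode tabulates only the photometric weights (the
spatial weights are constants and carry no quantization question). Nearest-
grid lookup over [0, |floor_db|] adds at most a half-step rounding error plus
an interpolation error of (max slope)·(grid spacing)/2 per coefficient; the
tests propagate that bound through the normalized weighted average and check
the filter output against it. The hardware trick of grouping the 7×7 mask by
its 8-fold radial symmetry is a resource optimization, not a numerical
change, and is implemented as plain summation.

### Threshold schedule: offsets above a per-bin background

Segmentation thresholds are dB offsets above a per-frequency-bin background
estimate (each row's 25th percentile over time), applied from the highest
offset down. An earlier design used global intensity percentiles of the
frame, but percentiles adapt to whatever texture the frame contains: on
noise-only frames the lower levels sit inside the noise distribution and
manufacture candidate objects out of smoothed noise clumps, which both
floods the classifier with ambiguous negatives and contradicts the intended
behavior that a quiet frame yields nothing. Measured on synthetic data,
residuals above the row background rarely exceed ~15 dB for pure breath
noise after bilateral smoothing, while the ridge of a wheeze at in-band SNR
10 dB sits at 20–28 dB; the schedule {24, 21, 18, 15} spans that gap. The
row-wise estimate also absorbs the strong spectral tilt of breath noise,
which no single global level can. Global-percentile thresholding remains
available (`seg_threshold_mode: percentile`).

### Morphological cleaning

Each binarized level is closed with an se_size×se_size square (bridging 1-px
gaps along ridges) and then opened with a 1×se_size *horizontal line*
element. Opening with a square would erase any structure thinner than
se_size rows — and wheeze ridges are often only 1–2 bins thick — whereas the
line element removes isolated specks and fragments shorter than se_size
columns while leaving thin horizontal ridges intact.

### Labeling and duplicate suppression

Connected components use the classic two-pass raster scan: provisional
labels, equivalence pairs resolved by union-find, final labels contiguous in
order of first appearance (deterministic). 8-connectivity is the default so
that sloped 1-px ridges stay connected; 4-connectivity is configurable.
Objects accepted at a higher threshold suppress lower-threshold objects that
share any pixel with them, so each episode is reported once, at the highest
threshold at which it passed all gates.

### Frame representative

When several objects survive, the frame is represented by the object with
the greatest *integrated linear power*, not the largest pixel count. The
harmonics of a wheeze form separate objects, and a harmonic lying on a
quieter part of the spectrum is often sliced lower on its skirt, giving it
more pixels than the fundamental even though it carries a quarter of the
energy; the power vote reliably selects the fundamental (98/100 correct
parameter recovery vs 64/100 with the area vote on the same seeded frames).
The area vote remains available (`aggregation: area`).

### Features and classifier

P_CY is the mean pixel row in Hz; P_T the bounding-box width in ms; P_S the
least-squares slope of per-column centroid frequency against time (0 for
single-column objects); P_AR the object area over its bounding box. Features
are standardized by training-set mean/sd before the RBF kernel
K(x,y) = exp(−‖x−y‖²/2σ²). Hyperparameters come from stratified k-fold CV
over a log₂ grid (C ∈ 2⁻³..2⁷, σ ∈ 2⁻⁴..2⁴ by default, 5 folds, seeded
shuffling; ties resolve to the smallest C, then the largest σ). The decision
threshold is 0 on the signed decision value — fixed-point rescalings of the
threshold that a hardware port might use are deliberately not reproduced.
Frames with no surviving object bypass the SVM as "normal": an all-zero
placeholder vector would poison training. Trained models serialize to JSON
(support vectors, dual coefficients, bias, scaler) and prediction recomputes
the kernel sum from the stored vectors, so a saved model is self-contained.

## Synthetic data: what it does and does not emulate

`wheezescan.synth` generates the labeled recordings the pipeline assumes:

- **background**: Gaussian noise low-passed at 1200 Hz (4th-order
  Butterworth) shaped by a raised-sine respiratory envelope
  (0.6 + 0.4·sin 2πf_b t, f_b = 0.25 Hz, random phase), RMS 0.05;
- **wheeze**: fundamental drawn from U(150, 600) Hz with 2 harmonics at
  halving amplitude (the worst-case top component stays below the 2205 Hz
  Nyquist even at maximum glide), duration U(300, 1200) ms, linear glide
  U(−50, 50) Hz/s, random onset such that the episode fits the frame, 10 ms
  cosine on/off ramps, scaled so the tone RMS sits `snr_db` (default 15) dB
  above the background RMS within the wheeze band.

Every frame is a pure function of (config, label, per-frame seed); datasets
regenerate bit-identically from their manifest.

Not modeled: crackles, heart sounds, friction/rubbing artifacts, amplitude
modulation of the wheeze itself, multiple simultaneous wheezes, room and
sensor coloration. Passing tests on this generator therefore demonstrate
that the implementation recovers what its own model class contains — tonal
ridges in low-passed noise — not clinical-grade performance; published
accuracies on hospital recordings are not reproducible without those
recordings. One consequence: all four feature subsets classify synthetic
data near ceiling (5-fold CV accuracy 0.98–1.0), so the ordering between
feature subsets reported on clinical data does not emerge here and is not
asserted by the tests.

## Numerical choices and degenerate inputs

- Spectrogram of an all-zero frame is exactly the dB floor; segmentation of
  a constant image returns nothing (thresholds are strict inequalities).
- Bilateral borders replicate the edge pixel; the center weight is 1, so
  denominators are bounded away from zero even with a coarse LUT.
- Ties in the dominant-object vote resolve to the first accepted object
  (raster/threshold order), so results are deterministic.
- Labels files, manifests, configs, and models are all plain text
  (CSV/JSON/YAML); WAV output is 16-bit PCM.
- Recordings at other sampling rates are polyphase-resampled on load; a
  trailing remainder shorter than 8820 samples is discarded with a log
  message.

## Evaluation

Wheeze is the positive class. PER is the geometric mean sqrt(SE·SP) — the
form consistent to every printed digit with the published confusion tables
this package's metric layer is checked against (an arithmetic mean is not).
Reports round to 6 decimals; the software-vs-quantized discordance rate
rounds to 4.

## Problem sizes used in the checks

The acceptance script and the heavier tests run the full pipeline on a
200-frame synthetic dataset (100 wheeze / 100 normal, SNR 15 dB): parameter
recovery over the 100 wheeze frames, an alternating train/test split for the
SVM, and a float-vs-quantized comparison over the test half. Oracle
equivalence suites use 100 seeded 12×12 images (bilateral vs a 4-nested-loop
reference) and 100 seeded 32×32 masks (two-pass labeling vs flood fill).

## Known limitations

- The 4410 Hz rate and 8820-sample unit are fixed by design; other rates are
  handled only by resampling on load.
- A wheeze occupying more than ~75% of a frame starts to contaminate the
  row-background estimate; offsets effectively shrink and very long events
  may be trimmed.
- Only one event per frame is classified (the dominant object); overlapping
  simultaneous wheezes collapse to the strongest.
- The CORSA duration rule is evaluated per 2-second unit, so an event
  straddling a frame boundary is judged on its within-frame extent.
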