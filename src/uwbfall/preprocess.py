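"""Echo preprocessing: normalize, background-subtract, denoise, log-scale.

The chain applied to every raw frame, in fixed order:

1. affine normalization of the raw frame into [0, 1] (the paired no-target
   reference frame is mapped with the *same* affine map so the subtraction
   operates on commensurate scales);
2. reference subtraction — removes static clutter, leaving the target echo
   and its multipath ghosts;
3. wavelet denoising — multi-level Daubechies-5 decomposition with soft
   universal thresholding of the detail coefficients;
4. logarithmic amplitude map followed by [0, 1] normalization — compresses
   the occasional very strong peak that would otherwise drown every weaker
   feature after normalization.

Training samples are additionally augmented by sliding the fast-time
sampling window along the range axis in fixed steps, which multiplies the
training set without touching labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pywt

from .radar_sim import ActivityLabel, RawRecording


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    ``decomposition_level=None`` resolves to ``floor(log2(n)) - 4`` (5 for
    800-bin frames), clamped to what the signal length supports.
    ``aug_step=10`` bins (~9 cm at full resolution) with ``n_aug=5`` windows
    expands a training split fivefold.  ``log_epsilon`` is the amplitude
    floor of the log map on the [0, 1]-normalized scale: 1e-3 (a -60 dB
    power floor) compresses strong peaks without flattening the echo
    amplitude modulations that carry activity information.
    """

    wavelet: str = "db5"
    decomposition_level: int | None = None
    threshold_rule: str = "universal"  # "universal" (soft) or "none"
    log_epsilon: float = 1e-3
    aug_step: int = 10
    n_aug: int = 5
    n_bins: int = 800
    wavelet_mode: str = "periodization"

    def validate(self) -> None:
        if self.n_aug < 1:
            raise ValueError("n_aug must be >= 1")
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")
        if self.aug_step < 0:
            raise ValueError("aug_step must be >= 0")
        if self.threshold_rule not in ("universal", "none"):
            raise ValueError("threshold_rule must be 'universal' or 'none'")


@dataclass
class ProcessedSample:
    """An M x n_bins matrix in [0, 1] with its labels and provenance."""

    matrix: np.ndarray  # (M, n_bins)
    label: ActivityLabel
    subject_id: str
    environment_id: str
    augmentation_index: int = 0

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# elementary stages


def normalize01(x: np.ndarray) -> np.ndarray:
    """Affine map of a vector onto [0, 1]; a constant vector maps to zeros."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo = x.min()
    span = x.max() - lo
    if span == 0:
        return np.zeros_like(x)
    return (x - lo) / span


def subtract_reference(frame: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Element-wise difference frame - reference (sign preserved)."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have equal length")
    return frame - reference


def _resolve_level(n: int, config: PreprocessConfig) -> int:
    if config.decomposition_level is not None:
        level = config.decomposition_level
    else:
        level = int(math.floor(math.log2(n))) - 4
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(config.wavelet).dec_len)
    return max(1, min(level, max(1, max_level)))


def _soft(c: np.ndarray, thr: np.ndarray) -> np.ndarray:
    return np.sign(c) * np.maximum(np.abs(c) - thr, 0.0)


def _denoise_matrix(x: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Wavelet-denoise along the last axis of a 1-D or 2-D array."""
    n = x.shape[-1]
    wav = pywt.Wavelet(config.wavelet)
    if n < wav.dec_len:
        raise ValueError(f"signal length {n} below wavelet support {wav.dec_len}")
    level = _resolve_level(n, config)
    coeffs = pywt.wavedec(x, wav, level=level, mode=config.wavelet_mode, axis=-1)
    if config.threshold_rule == "universal":
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest), axis=-1, keepdims=True) / 0.6745
        thr = sigma * math.sqrt(2.0 * math.log(n))
        coeffs = [coeffs[0]] + [_soft(c, thr) for c in coeffs[1:]]
    rec = pywt.waverec(coeffs, wav, mode=config.wavelet_mode, axis=-1)
    return rec[..., :n]


def wavelet_denoise(signal: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Soft-threshold wavelet denoising of one fast-time vector.

    The noise level is estimated from the finest detail band as
    ``median(|d|) / 0.6745`` and every detail coefficient is soft-thresholded
    at the universal threshold ``sigma * sqrt(2 ln n)``.
    """
    config = config or PreprocessConfig()
    config.validate()
    signal = np.asarray(signal, dtype=float)
    return _denoise_matrix(signal, config)


def log_amplitude_map(signal: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Map ``log(|x| + eps)`` onto [0, 1]; monotone in |x|."""
    config = config or PreprocessConfig()
    config.validate()
    signal = np.asarray(signal, dtype=float)
    return normalize01(np.log(np.abs(signal) + config.log_epsilon))


# ---------------------------------------------------------------------------
# full per-recording chain


def _preprocess_window(frames: np.ndarray, reference: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Run the full chain on an (M, n_bins) window; returns values in [0, 1]."""
    lo = frames.min(axis=-1, keepdims=True)
    span = frames.max(axis=-1, keepdims=True) - lo
    # frame and its reference share one affine map, so the difference is
    # simply (frame - reference) / span; degenerate constant frames -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.where(span > 0, (frames - reference[None, :]) / np.where(span > 0, span, 1.0), 0.0)
    den = _denoise_matrix(diff, config)
    y = np.log(np.abs(den) + config.log_epsilon)
    ylo = y.min(axis=-1, keepdims=True)
    yspan = y.max(axis=-1, keepdims=True) - ylo
    out = np.where(yspan > 0, (y - ylo) / np.where(yspan > 0, yspan, 1.0), 0.0)
    return out


def augment_translate(recording: RawRecording, config: PreprocessConfig) -> list[ProcessedSample]:
    """Slide the n_bins sampling window in aug_step-bin increments.

    Produces ``n_aug`` fully preprocessed samples per raw recording, window
    starts at bins 0, aug_step, ..., (n_aug-1)*aug_step.  Labels are
    unchanged; intended for the training split only.
    """
    config.validate()
    need = config.n_bins + (config.n_aug - 1) * config.aug_step
    if recording.n_bins_raw < need:
        raise ValueError(
            f"raw fast-time length {recording.n_bins_raw} < required {need} "
            f"for n_aug={config.n_aug}, aug_step={config.aug_step}"
        )
    out = []
    for j in range(config.n_aug):
        o = j * config.aug_step
        mat = _preprocess_window(
            recording.frames[:, o : o + config.n_bins],
            recording.reference[o : o + config.n_bins],
            config,
        )
        out.append(
            ProcessedSample(
                matrix=mat,
                label=recording.label,
                subject_id=recording.subject_id,
                environment_id=recording.environment_id,
                augmentation_index=j,
            )
        )
    return out


def preprocess_recording(
    recording: RawRecording, config: PreprocessConfig, augment: bool = False
) -> list[ProcessedSample]:
    """Preprocess one recording; with ``augment`` apply window translation."""
    config.validate()
    if augment:
        return augment_translate(recording, config)
    if recording.n_bins_raw < config.n_bins:
        raise ValueError("raw fast-time length below the sampling window width")
    return augment_translate(recording, replace(config, n_aug=1))


def preprocess_dataset(
    recordings: list[RawRecording], config: PreprocessConfig, augment: bool = False
) -> list[ProcessedSample]:
    out: list[ProcessedSample] = []
    for rec in recordings:
        out.extend(preprocess_recording(rec, config, augment=augment))
    return out


def trim_frames(sample: ProcessedSample, target_m: int) -> ProcessedSample:
    """Reduce a sample to ``target_m`` frames by alternating end removals.

    Frames are removed alternately from the end then the start (the final
    frame goes first), preserving temporal order — so an even number of
    removals is symmetric about the sample center.
    """
    m = sample.n_frames
    if not (1 <= target_m <= m):
        raise ValueError(f"target_m must be in [1, {m}]")
    lo, hi = 0, m
    remove_end = True
    while hi - lo > target_m:
        if remove_end:
            hi -= 1
        else:
            lo += 1
        remove_end = not remove_end
    return replace(sample, matrix=sample.matrix[lo:hi])
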