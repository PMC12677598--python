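"""Raw session -> z-scored high-gamma PSD feature matrix.

The stage order is fixed: impedance exclusion, notch filtering of the line
frequency and harmonics, common average referencing, anti-aliased
downsampling, 100-ms binning with a per-bin periodogram, and train-segment
z-scoring.  :func:`preprocess_session` runs the stages in that order and is
the only entry point the rest of the pipeline uses.

The per-bin PSD estimator is a single Hann-windowed periodogram: at the
default 500 Hz / 100 ms a bin holds 50 samples, which leaves no room for
Welch segmentation.  The high-gamma feature is the mean PSD over frequency
bins whose centre lies in [70, 150] Hz inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .core_io import RunConfig, SessionRecording
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Bins x channels z-scored high-gamma power features."""

    values: np.ndarray           # (n_bins, n_channels)
    bin_ms: float
    band: tuple
    channel_ids: np.ndarray      # retained channel ids, layout order
    norm_mean: np.ndarray        # per-channel, from the training segment
    norm_std: np.ndarray
    bin_timestamps: np.ndarray   # right edge of each bin, s
    zero_variance: np.ndarray = None   # flagged degenerate channels

    def __post_init__(self):
        if self.zero_variance is None:
            self.zero_variance = np.zeros(self.values.shape[1], dtype=bool)
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("feature matrix contains non-finite values")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def select_channels(self, indices) -> "FeatureMatrix":
        """Restrict to a channel subset (columns), keeping normalization stats."""
        indices = np.asarray(indices)
        return FeatureMatrix(
            values=self.values[:, indices], bin_ms=self.bin_ms, band=self.band,
            channel_ids=self.channel_ids[indices],
            norm_mean=self.norm_mean[indices], norm_std=self.norm_std[indices],
            bin_timestamps=self.bin_timestamps,
            zero_variance=self.zero_variance[indices],
        )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def exclude_high_impedance(session: SessionRecording,
                           threshold_mohm: float = 1.0) -> np.ndarray:
    """Mask of channels whose impedance is at or below the threshold.

    Signals are untouched; the mask feeds the common-average reference set
    and the final channel selection.
    """
    mask = session.impedances <= threshold_mohm
    if not mask.any():
        logger.warning("impedance screening at %.2f MOhm excluded every channel",
                       threshold_mohm)
    return mask


def notch_filter(signals: np.ndarray, fs: float, base_hz: float = 50.0,
                 n_harmonics: int = 4, q: float = 30.0) -> np.ndarray:
    """Zero-phase cascaded IIR notches at ``base_hz`` and its harmonics."""
    if base_hz * n_harmonics >= fs / 2:
        raise InvalidArgumentError(
            f"harmonic {base_hz * n_harmonics} Hz at or above Nyquist {fs / 2} Hz")
    out = np.asarray(signals, dtype=float)
    for h in range(1, n_harmonics + 1):
        b, a = sps.iirnotch(base_hz * h, Q=q, fs=fs)
        out = sps.filtfilt(b, a, out, axis=-1)
    return out


def common_average_reference(signals: np.ndarray,
                             mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract the across-channel mean of the retained channels per sample.

    Excluded channels pass through unreferenced (they stay excluded
    downstream); the retained channels' mean is exactly zero afterwards.
    """
    signals = np.asarray(signals, dtype=float)
    if mask is None:
        mask = np.ones(signals.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise InvalidArgumentError("common average reference needs >= 2 retained channels")
    out = signals.copy()
    out[mask] -= signals[mask].mean(axis=0, keepdims=True)
    return out


def resample_to(signals: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased polyphase resampling to a lower rate (identity if equal)."""
    if fs_out > fs_in:
        raise InvalidArgumentError("no upsampling path: fs_out must be <= fs_in")
    if fs_out == fs_in:
        return np.asarray(signals, dtype=float)
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(np.asarray(signals, dtype=float),
                             frac.numerator, frac.denominator, axis=-1)


def extract_hg_features(signals: np.ndarray, fs: float, bin_ms: float = 100.0,
                        band: tuple = (70.0, 150.0)) -> tuple:
    """Per-bin Hann periodogram, averaged over the high-gamma band.

    Returns ``(raw_features, bin_edges)`` where ``raw_features`` is
    bins x channels and ``bin_edges`` holds each bin's right edge in seconds.
    A trailing partial bin is dropped.
    """
    if not (0 < band[0] < band[1] < fs / 2):
        raise InvalidArgumentError(f"band {band} outside (0, {fs / 2}) Hz")
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_per_bin = int(round(fs * bin_ms / 1000.0))
    if n_per_bin < 8:
        raise InvalidArgumentError("bin must hold at least 8 samples")
    n_bins = signals.shape[1] // n_per_bin
    if n_bins == 0:
        raise InvalidArgumentError("signal shorter than one bin")
    x = signals[:, :n_bins * n_per_bin].reshape(signals.shape[0], n_bins, n_per_bin)
    freqs, psd = sps.periodogram(x, fs=fs, window="hann", axis=-1)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise InvalidArgumentError(f"no periodogram bins inside band {band}")
    feats = psd[:, :, in_band].mean(axis=-1).T          # (bins, channels)
    edges = (np.arange(n_bins) + 1) * (n_per_bin / fs)
    return feats, edges


def zscore_features(raw: np.ndarray, train_range: slice | tuple,
                    bin_ms: float, band: tuple, channel_ids: np.ndarray,
                    bin_timestamps: np.ndarray) -> FeatureMatrix:
    """Z-score with statistics from the training bins only (no leakage).

    Zero-variance channels are set to all-zero and flagged instead of raising:
    a dead channel can survive impedance screening, and downstream stages
    treat a zero column as uninformative.
    """
    raw = np.asarray(raw, dtype=float)
    if isinstance(train_range, tuple):
        train_range = slice(*train_range)
    train = raw[train_range]
    if train.shape[0] == 0:
        raise InvalidArgumentError("training range is empty")
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    zero_var = std == 0
    std_safe = np.where(zero_var, 1.0, std)
    values = (raw - mean) / std_safe
    values[:, zero_var] = 0.0
    if zero_var.any():
        logger.warning("%d zero-variance channel(s) flagged and zeroed",
                       int(zero_var.sum()))
    return FeatureMatrix(
        values=values, bin_ms=bin_ms, band=band,
        channel_ids=np.asarray(channel_ids),
        norm_mean=mean, norm_std=np.where(zero_var, 0.0, std),
        bin_timestamps=np.asarray(bin_timestamps),
        zero_variance=zero_var,
    )


def apply_normalization(raw: np.ndarray, reference: FeatureMatrix,
                        bin_timestamps: np.ndarray) -> FeatureMatrix:
    """Normalize a new session's raw features with stored statistics (no re-fit).

    This is the cross-session recalibration path: the training-session
    mean/std are reused verbatim.
    """
    std_safe = np.where(reference.norm_std == 0, 1.0, reference.norm_std)
    values = (np.asarray(raw, dtype=float) - reference.norm_mean) / std_safe
    values[:, reference.norm_std == 0] = 0.0
    return FeatureMatrix(
        values=values, bin_ms=reference.bin_ms, band=reference.band,
        channel_ids=reference.channel_ids, norm_mean=reference.norm_mean,
        norm_std=reference.norm_std, bin_timestamps=np.asarray(bin_timestamps),
        zero_variance=reference.norm_std == 0,
    )


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------

PIPELINE_ORDER = ("exclude", "notch", "car", "resample", "psd", "zscore")


def preprocess_session(session: SessionRecording,
                       config: RunConfig | None = None,
                       car_reference_mask: np.ndarray | None = None) -> FeatureMatrix:
    """Run the full fixed-order preprocessing pipeline on one session.

    ``car_reference_mask`` pins the common-average reference set explicitly
    (used by the subsampling experiments, which reference once over the full
    retained array and then sub-select features); by default the reference
    set is the impedance-retained channels.
    """
    cfg = config or RunConfig()
    stages_run = []

    mask = exclude_high_impedance(session, cfg.impedance_threshold)
    stages_run.append("exclude")

    x = notch_filter(session.signals, session.fs, cfg.notch_base, cfg.n_harmonics)
    stages_run.append("notch")

    ref = car_reference_mask if car_reference_mask is not None else mask
    x = common_average_reference(x, ref)
    stages_run.append("car")

    x = resample_to(x, session.fs, cfg.target_fs)
    stages_run.append("resample")

    x = x[mask]
    raw, edges = extract_hg_features(x, cfg.target_fs, cfg.bin_ms, cfg.band)
    stages_run.append("psd")

    n_train = int(np.floor(cfg.split_ratio * raw.shape[0]))
    fm = zscore_features(raw, slice(0, n_train), cfg.bin_ms, cfg.band,
                         channel_ids=session.layout.channel_ids[mask],
                         bin_timestamps=edges)
    stages_run.append("zscore")

    assert tuple(stages_run) == PIPELINE_ORDER, "preprocessing stage order violated"
    return fm
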