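"""Spectral features for epoch-wise sleep staging.

Power density spectra are Welch estimates over non-overlapping 5-s Hann
windows (four per 20-s epoch, six per 30-s epoch), giving a 0.2 Hz
frequency resolution at 128 Hz. Spectrograms are restricted to 0.8-40 Hz.

Each epoch is summarised by 20 engineered features covering EEG band
powers and their ratios, eye movements and muscle tone. No epochs are
excluded: artifact-bearing epochs carry information (wake is almost always
accompanied by movement artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import signal as sps

from .core import Recording

#: Floor added inside log10 so all-zero epochs stay finite (microvolt^2).
LOG_EPS = 1e-12

WELCH_WINDOW_S = 5.0


@dataclass
class PSD:
    """One-sided power spectral density, 0.2 Hz spacing, microvolt^2/Hz."""

    freqs_hz: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs_hz.shape != self.power.shape[-1:]:
            raise ValueError("frequency grid and power mismatch")

    def band_power(self, lo: float, hi: float, closed_hi: bool = False) -> Union[float, np.ndarray]:
        """Integrated power over [lo, hi) Hz (hi inclusive if requested)."""
        df = self.freqs_hz[1] - self.freqs_hz[0]
        sel = (self.freqs_hz >= lo - 1e-9) & (
            (self.freqs_hz <= hi + 1e-9) if closed_hi else (self.freqs_hz < hi - 1e-9)
        )
        return self.power[..., sel].sum(axis=-1) * df


@dataclass
class Spectrogram:
    """Epochs x frequency-bin power matrix restricted to 0.8-40 Hz."""

    freqs_hz: np.ndarray
    power: np.ndarray  # (n_epochs, n_bins)
    epoch_len_s: int

    def log10(self) -> np.ndarray:
        """Log-scaled power for display; 0 dB corresponds to 1 uV^2/Hz."""
        return np.log10(self.power + LOG_EPS)


FEATURE_NAMES: tuple[str, ...] = (
    "eeg_log_slow_osc_0.8_1",
    "eeg_log_delta_1_4",
    "eeg_log_theta_4_8",
    "eeg_log_alpha_8_12",
    "eeg_log_sigma_12_14",
    "eeg_log_beta1_14_20",
    "eeg_log_beta2_20_30",
    "eeg_ratio_delta_theta",
    "eeg_ratio_delta_alpha",
    "eeg_ratio_sigma_theta",
    "eeg_ratio_slowfast",
    "eeg_spectral_edge_95",
    "eeg_log_total_0.8_40",
    "eeg_amplitude_range",
    "eog_crosscorr_lag0",
    "eog_log_slow_0.3_2",
    "eog_log_fast_2_6",
    "eog_rem_event_count",
    "emg_log_power_15_30",
    "emg_power_ratio_median",
)


@dataclass
class FeatureMatrix:
    """Epochs x 20 engineered features aligned to a hypnogram grid."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    epoch_len_s: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix must be epochs x n_features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.index.name = "epoch_index"
        df.to_csv(path)


# ---------------------------------------------------------------------------
# Spectral estimation
# ---------------------------------------------------------------------------


def welch_psd(epoch_samples: np.ndarray, fs_hz: float, window_len_s: float = WELCH_WINDOW_S) -> PSD:
    """Welch PSD: mean over non-overlapping Hann-windowed 5-s segments.

    Epoch length must be an integer multiple of the window length (four
    windows for a 20-s epoch, six for 30 s). Per-window mean detrending is
    applied; the density scaling satisfies Parseval: sum(PSD) * df equals
    the signal's mean square (up to window leakage).
    """
    x = np.asarray(epoch_samples, dtype=float)
    nper = int(round(window_len_s * fs_hz))
    if x.shape[-1] < nper:
        raise ValueError(f"epoch of {x.shape[-1]} samples is shorter than one {window_len_s}-s window")
    if x.shape[-1] % nper:
        raise ValueError("epoch length must be an integer multiple of the window length")
    freqs, power = sps.welch(
        x,
        fs=fs_hz,
        window="hann",
        nperseg=nper,
        noverlap=0,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return PSD(freqs, power)


def spectrogram(recording: Recording, epoch_len_s: int) -> Spectrogram:
    """Per-epoch EEG Welch spectra cropped to the 0.8-40 Hz range."""
    ch = recording.channel("EEG")
    n = int(round(ch.fs_hz * epoch_len_s))
    n_epochs = ch.samples.size // n
    blocks = ch.samples[: n_epochs * n].reshape(n_epochs, n)
    psd = welch_psd(blocks, ch.fs_hz, WELCH_WINDOW_S)
    sel = (psd.freqs_hz >= 0.8 - 1e-9) & (psd.freqs_hz <= 40.0 + 1e-9)
    return Spectrogram(psd.freqs_hz[sel], psd.power[:, sel], epoch_len_s)


def emg_power(emg_epoch: np.ndarray, fs_hz: float) -> Union[float, np.ndarray]:
    """Muscle-tone scalar: integrated EMG power in the 15-30 Hz band (uV^2)."""
    psd = welch_psd(emg_epoch, fs_hz, WELCH_WINDOW_S)
    return psd.band_power(15.0, 30.0)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def _log(x: np.ndarray) -> np.ndarray:
    return np.log10(x + LOG_EPS)


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _spectral_edge(psd: PSD, lo: float = 0.8, hi: float = 40.0, q: float = 0.95) -> np.ndarray:
    """Frequency below which q of the 0.8-40 Hz power lies, per epoch."""
    sel = (psd.freqs_hz >= lo - 1e-9) & (psd.freqs_hz <= hi + 1e-9)
    f = psd.freqs_hz[sel]
    p = psd.power[..., sel]
    cum = np.cumsum(p, axis=-1)
    total = cum[..., -1:]
    total = np.where(total <= 0, 1.0, total)
    idx = np.argmax(cum / total >= q, axis=-1)
    return f[idx]


def _rem_event_count(eog_diff_bp: np.ndarray, threshold_uv: float = 25.0) -> np.ndarray:
    """Rapid-eye-movement events per epoch: excursions of the band-passed
    EOG difference signal beyond +-threshold (counted once per excursion)."""
    above = np.abs(eog_diff_bp) > threshold_uv
    starts = above[..., 1:] & ~above[..., :-1]
    return starts.sum(axis=-1) + above[..., :1].sum(axis=-1)


def extract_features(recording: Recording, epoch_len_s: int) -> FeatureMatrix:
    """The 20-component feature vector per epoch.

    Features 1-7: log EEG band powers (slow oscillation 0.8-1, delta 1-4,
    theta 4-8, alpha 8-12, sigma 12-14, beta1 14-20, beta2 20-30 Hz);
    8-11: log band-power ratios delta/theta, delta/alpha, sigma/theta and
    (delta+theta)/(alpha+sigma+beta1); 12: 95% spectral edge frequency;
    13: log total power 0.8-40 Hz; 14: epoch amplitude range (p99 - p1);
    15: lag-0 cross-correlation of the two EOG channels band-passed
    0.3-5 Hz (eye movements anti-correlate); 16/17: log EOG slow
    (0.3-2 Hz) and fast (2-6 Hz) band powers (mean of both channels);
    18: rapid-eye-movement event count from the band-passed EOG difference;
    19: log EMG power 15-30 Hz; 20: EMG power relative to its recording
    median. Band edges are half-open [lo, hi) except the final 40 Hz edge.
    """
    for role in ("EEG", "EOG_L", "EOG_R", "EMG"):
        if not recording.has_channel(role):
            raise KeyError(f"feature extraction requires channel {role}; available: {recording.roles}")
    eeg = recording.channel("EEG")
    eog_l = recording.channel("EOG_L")
    eog_r = recording.channel("EOG_R")
    emg = recording.channel("EMG")
    fs = eeg.fs_hz
    n = int(round(fs * epoch_len_s))
    n_epochs = min(int(c.samples.size // (c.fs_hz * epoch_len_s)) for c in recording.channels)

    def blocks(ch) -> np.ndarray:
        m = int(round(ch.fs_hz * epoch_len_s))
        return ch.samples[: n_epochs * m].reshape(n_epochs, m)

    eeg_b, eogl_b, eogr_b, emg_b = blocks(eeg), blocks(eog_l), blocks(eog_r), blocks(emg)

    psd = welch_psd(eeg_b, fs)
    slow_osc = psd.band_power(0.8, 1.0)
    delta = psd.band_power(1.0, 4.0)
    theta = psd.band_power(4.0, 8.0)
    alpha = psd.band_power(8.0, 12.0)
    sigma = psd.band_power(12.0, 14.0)
    beta1 = psd.band_power(14.0, 20.0)
    beta2 = psd.band_power(20.0, 30.0)
    total = psd.band_power(0.8, 40.0, closed_hi=True)

    edge = _spectral_edge(psd)
    amp_range = np.percentile(eeg_b, 99, axis=-1) - np.percentile(eeg_b, 1, axis=-1)

    # EOG features on the slow eye-movement band
    eogl_bp = _bandpass(eogl_b, fs, 0.3, 5.0)
    eogr_bp = _bandpass(eogr_b, fs, 0.3, 5.0)
    num = (eogl_bp * eogr_bp).mean(axis=-1)
    den = eogl_bp.std(axis=-1) * eogr_bp.std(axis=-1)
    xcorr = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    psd_l = welch_psd(eogl_b, fs)
    psd_r = welch_psd(eogr_b, fs)
    eog_slow = 0.5 * (psd_l.band_power(0.3, 2.0) + psd_r.band_power(0.3, 2.0))
    eog_fast = 0.5 * (psd_l.band_power(2.0, 6.0) + psd_r.band_power(2.0, 6.0))
    rem_count = _rem_event_count(eogl_bp - eogr_bp)

    emg_p = np.atleast_1d(emg_power(emg_b, emg.fs_hz))
    emg_median = np.median(emg_p)
    emg_ratio = emg_p / (emg_median if emg_median > 0 else 1.0)

    values = np.column_stack(
        [
            _log(slow_osc),
            _log(delta),
            _log(theta),
            _log(alpha),
            _log(sigma),
            _log(beta1),
            _log(beta2),
            _log(delta) - _log(theta),
            _log(delta) - _log(alpha),
            _log(sigma) - _log(theta),
            _log(delta + theta) - _log(alpha + sigma + beta1),
            edge,
            _log(total),
            amp_range,
            xcorr,
            _log(eog_slow),
            _log(eog_fast),
            rem_count.astype(float),
            _log(emg_p),
            emg_ratio,
        ]
    )
    return FeatureMatrix(values, FEATURE_NAMES, epoch_len_s)
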