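"""ECG heart-rate chain and EEG epoch screening.

Two causal signal chains feed the metric time series:

* ECG: band-pass filter (15–35 Hz, 4th-order recursive) to sharpen the QRS
  complex against the T wave, adaptive peak detection from a sample-by-sample
  running mean and standard deviation, per-beat quality assessment from the
  dispersion of up to six consecutive RR intervals, and heart rate as 60/RR
  beats per minute resampled to 1-s epochs.
* EEG: per-1-s-epoch log power spectral densities on 1-Hz bins, relative PSD
  against the total 1–40 Hz power, and a two-criterion muscle-artifact (EMG)
  screen — elevated 35–40 Hz power AND an elevated square root of the summed
  70–128 Hz power — whose flagged epochs are discarded downstream.

Both chains run forward-only (no zero-phase filtering): the original
acquisition was a causal real-time system and the package keeps that
behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

ECG_BAND_HZ = (15.0, 35.0)
EEG_BAND_HZ = (0.5, 65.0)
NOTCH_HZ = (50.0, 60.0, 100.0, 120.0)

# Peak-detector defaults: 2-s running-statistics window, mean + 3 sd
# threshold, 250 ms refractory — standard QRS-detection practice.
PEAK_WINDOW_S = 2.0
PEAK_K = 3.0
REFRACTORY_S = 0.25

BEAT_QUALITY_K = 3.0
BEAT_QUALITY_SD_FLOOR_S = 0.010  # RR dispersion floor, 10 ms
BEAT_QUALITY_HISTORY = 6

PSD_LOG_FLOOR = 1e-12
PSD_LOW_BAND = (1, 40)    # 1-Hz bins kept as the log-PSD profile
EMG_BAND_A = (35, 40)     # criterion (a) band
EMG_BAND_B = (70, 128)    # criterion (b) band
#: Default EMG-screen cut-offs, calibrated on the synthetic generator so
#: broadband muscle bursts trip both criteria while narrow-band (alpha-like)
#: activity trips neither. Real deployments must re-calibrate on their data.
EMG_THETA_35_40 = float(np.log(1e-4))
EMG_THETA_70_128 = 0.05


@dataclass
class ECGRecord:
    """Single-lead ECG amplitude series."""

    samples: np.ndarray
    sampling_rate: float = 256.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class RPeakList:
    """Detected R-peaks with RR intervals and per-beat quality flags.

    ``rr_intervals[k]`` is the interval ending at ``peak_times[k]``; the first
    beat has no interval (NaN). ``quality_flags[k]`` is True for beats whose
    RR is consistent with the recent rhythm.
    """

    peak_times: np.ndarray
    quality_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=np.float64)
        if len(self.peak_times) > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")
        if self.quality_flags is None:
            self.quality_flags = np.ones(len(self.peak_times), dtype=bool)
        else:
            self.quality_flags = np.asarray(self.quality_flags, dtype=bool)

    def __len__(self) -> int:
        return len(self.peak_times)

    @property
    def rr_intervals(self) -> np.ndarray:
        rr = np.full(len(self.peak_times), np.nan)
        if len(self.peak_times) > 1:
            rr[1:] = np.diff(self.peak_times)
        return rr


@dataclass
class EpochPSD:
    """Log power spectral density of one 1-s epoch on 1-Hz bins."""

    epoch_start: int
    log_abs_psd: np.ndarray          # bins PSD_LOW_BAND[0]..PSD_LOW_BAND[1] Hz
    power_35_40: np.ndarray          # raw power, criterion (a) bins
    power_70_128: np.ndarray         # raw power, criterion (b) bins
    raw_power: np.ndarray = field(repr=False, default=None)  # all bins 0..Nyquist


def bandpass_ecg(ecg: ECGRecord, band_hz: tuple[float, float] = ECG_BAND_HZ) -> ECGRecord:
    """4th-order recursive Butterworth band-pass, applied forward-only."""
    fs = ecg.sampling_rate
    if fs < 100:
        raise ValueError("sampling_rate must be >= 100 Hz")
    if band_hz[1] >= fs / 2:
        raise ValueError(f"passband {band_hz} infeasible at {fs} Hz")
    sos = sps.butter(2, band_hz, btype="bandpass", fs=fs, output="sos")
    return ECGRecord(sps.sosfilt(sos, ecg.samples), fs)


def detect_r_peaks(
    ecg: ECGRecord,
    window_s: float = PEAK_WINDOW_S,
    k: float = PEAK_K,
    refractory_s: float = REFRACTORY_S,
) -> RPeakList:
    """Adaptive-threshold peak detection on a (filtered) ECG.

    A sample is a peak when it is a local maximum exceeding the causal
    running mean plus ``k`` running standard deviations (window ``window_s``),
    and no peak was accepted within ``refractory_s`` before it.  A flat
    signal yields an empty list.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = ecg.samples
    fs = ecg.sampling_rate
    w = max(int(round(window_s * fs)), 2)
    s = pd.Series(x)
    mean = s.rolling(w, min_periods=1).mean().to_numpy()
    std = s.rolling(w, min_periods=1).std(ddof=0).to_numpy()
    std[~np.isfinite(std)] = 0.0
    thresh = mean + k * std

    if len(x) < 3:
        return RPeakList(np.empty(0))
    local_max = np.zeros(len(x), dtype=bool)
    local_max[1:-1] = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])
    cand = np.flatnonzero(local_max & (x > thresh) & (std > 0))

    accepted: list[int] = []
    ref = refractory_s * fs
    for c in cand:
        if not accepted or c - accepted[-1] > ref:
            accepted.append(int(c))
    return RPeakList(np.asarray(accepted, dtype=float) / fs)


def assess_beat_quality(
    peaks: RPeakList,
    k_q: float = BEAT_QUALITY_K,
    history: int = BEAT_QUALITY_HISTORY,
    sd_floor_s: float = BEAT_QUALITY_SD_FLOOR_S,
) -> RPeakList:
    """Flag beats whose RR deviates from the recent rhythm.

    A beat is low-quality when its RR differs from the mean of the preceding
    up-to-``history`` RR intervals by more than ``k_q`` times their standard
    deviation (floored at ``sd_floor_s`` so a metronomic rhythm does not
    produce a zero tolerance).  Beats with fewer than two preceding intervals
    pass by default.
    """
    rr = peaks.rr_intervals
    flags = np.ones(len(peaks), dtype=bool)
    for i in range(len(peaks)):
        if not np.isfinite(rr[i]):
            continue
        prior = rr[max(1, i - history) : i]
        prior = prior[np.isfinite(prior)]
        if len(prior) < 2:
            continue
        sd = max(float(prior.std(ddof=0)), sd_floor_s)
        if abs(rr[i] - prior.mean()) > k_q * sd:
            flags[i] = False
    return RPeakList(peaks.peak_times, flags)


def heart_rate_series(peaks: RPeakList, duration_s: int | None = None) -> np.ndarray:
    """Per-1-s-epoch heart rate (bpm) carried forward from the latest beat.

    Per-beat HR is exactly 60/RR; low-quality beats contribute no value.
    Epoch ``t`` takes the HR of the most recent usable beat completed by the
    end of the epoch; epochs before the second peak are NaN.  A list with a
    single peak yields an all-NaN series.
    """
    if duration_s is None:
        duration_s = int(np.ceil(peaks.peak_times[-1])) if len(peaks) else 0
    hr = np.full(duration_s, np.nan)
    rr = peaks.rr_intervals
    usable = np.isfinite(rr) & peaks.quality_flags
    beat_t = peaks.peak_times[usable]
    beat_hr = 60.0 / rr[usable]
    if len(beat_t) == 0:
        return hr
    j = -1
    for t in range(duration_s):
        while j + 1 < len(beat_t) and beat_t[j + 1] < t + 1:
            j += 1
        if j >= 0:
            hr[t] = beat_hr[j]
    return hr


def ecg_to_heart_rate(ecg: ECGRecord, duration_s: int | None = None, **detect_kwargs) -> np.ndarray:
    """Full ECG chain: band-pass → peak detection → quality → per-second HR."""
    peaks = detect_r_peaks(bandpass_ecg(ecg), **detect_kwargs)
    peaks = assess_beat_quality(peaks)
    return heart_rate_series(peaks, duration_s)


def match_peaks(
    detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.05
) -> tuple[float, float]:
    """Greedy one-to-one matching of detected to true peak times.

    Returns ``(recall, precision)`` with matches counted within ``tol_s``.
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(len(detected), dtype=bool)
    hits = 0
    for t in truth:
        if len(detected) == 0:
            break
        d = np.abs(detected - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            used[j] = True
            hits += 1
    recall = hits / len(truth) if len(truth) else 1.0
    precision = hits / len(detected) if len(detected) else 1.0
    return recall, precision


# ----------------------------------------------------------------------------
# EEG epoch screening

def compute_epoch_psd(block: np.ndarray, sampling_rate: float, epoch_start: int = 0) -> EpochPSD:
    """Periodogram of one 1-s block on 1-Hz bins.

    The block must hold exactly one second of samples, so the FFT bins fall
    on integer frequencies.  Power is normalized so the bins sum to the mean
    squared amplitude (Parseval); the stored profile is the natural log of
    the 1–40 Hz bins with powers floored at 1e-12.
    """
    block = np.asarray(block, dtype=np.float64)
    n = int(round(sampling_rate))
    if len(block) != n:
        raise ValueError(f"expected {n} samples (1 s at {sampling_rate} Hz), got {len(block)}")
    spec = np.fft.rfft(block)
    power = np.abs(spec) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated

    lo, hi = PSD_LOW_BAND
    log_psd = np.log(np.maximum(power[lo : hi + 1], PSD_LOG_FLOOR))
    a_lo, a_hi = EMG_BAND_A
    b_lo, b_hi = EMG_BAND_B
    nyq = len(power) - 1
    return EpochPSD(
        epoch_start=epoch_start,
        log_abs_psd=log_psd,
        power_35_40=power[a_lo : min(a_hi, nyq) + 1],
        power_70_128=power[b_lo : min(b_hi, nyq) + 1],
        raw_power=power,
    )


def relative_psd(psd: EpochPSD) -> np.ndarray:
    """Per-bin log power relative to the total 1–40 Hz power.

    Computed in the log domain as ``log(bin) − log(total)``, i.e. the log of
    each bin's share of the band power.
    """
    lo, hi = PSD_LOW_BAND
    band = psd.raw_power[lo : hi + 1]
    total = float(band.sum())
    if total <= 0:
        raise ValueError("zero total 1-40 Hz power")
    return np.log(np.maximum(band, PSD_LOG_FLOOR)) - np.log(total)


def detect_emg_epoch(
    psd: EpochPSD,
    theta_35_40: float = EMG_THETA_35_40,
    theta_70_128: float = EMG_THETA_70_128,
) -> bool:
    """Two-criterion muscle-artifact test for one epoch.

    Flags the epoch when (a) the mean log power over the 35–40 Hz bins
    exceeds ``theta_35_40`` AND (b) the square root of the summed
    70–128 Hz power exceeds ``theta_70_128``.
    """
    crit_a = float(np.mean(np.log(np.maximum(psd.power_35_40, PSD_LOG_FLOOR)))) > theta_35_40
    crit_b = float(np.sqrt(psd.power_70_128.sum())) > theta_70_128
    return crit_a and crit_b


def screen_epochs(
    eeg: np.ndarray,
    sampling_rate: float,
    theta_35_40: float = EMG_THETA_35_40,
    theta_70_128: float = EMG_THETA_70_128,
) -> np.ndarray:
    """Validity mask over whole 1-s epochs of a raw EEG trace.

    True means the epoch is free of detected EMG artifacts.
    """
    n = int(round(sampling_rate))
    n_epochs = len(eeg) // n
    mask = np.ones(n_epochs, dtype=bool)
    for t in range(n_epochs):
        psd = compute_epoch_psd(eeg[t * n : (t + 1) * n], sampling_rate, epoch_start=t)
        if detect_emg_epoch(psd, theta_35_40, theta_70_128):
            mask[t] = False
    return mask


def preprocess_eeg(eeg: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Optional raw-EEG front end: 0.5–65 Hz band-pass plus power-line notches.

    Inert for the synthetic metric pathway, which never produces raw EEG;
    provided for raw-signal input.
    """
    sos = sps.butter(2, EEG_BAND_HZ, btype="bandpass", fs=sampling_rate, output="sos")
    x = sps.sosfilt(sos, np.asarray(eeg, dtype=np.float64))
    for f0 in NOTCH_HZ:
        if f0 < sampling_rate / 2:
            b, a = sps.iirnotch(f0, Q=30.0, fs=sampling_rate)
            x = sps.lfilter(b, a, x)
    return x
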