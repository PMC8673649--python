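"""B-call detection by spectrogram cross-correlation.

The first harmonic of the northeast Pacific blue whale B call sweeps down
almost linearly from ~15.7 Hz to ~14.4 Hz over ~10 s.  Detection proceeds in
four steps: (1) a spectrogram with a 2-s Hann window and 80% overlap (0.4 s
frames, 0.5 Hz bins); (2) per-frequency median subtraction to suppress
stationary noise; (3) cross-correlation with a swept-tone kernel whose
cross-frequency profile is the second derivative of a Gaussian, giving bands
of negative weight above and below the call frequency and a zero-sum kernel;
(4) peak picking on the log10 recognition-score series with a minimum peak
separation of 10 s.

The absolute scale of the recognition score is arbitrary; here the normalized
spectrogram is rescaled so its 90th percentile equals one before the kernel
inner product, and the default threshold of 2.2 is a configuration value to
be recalibrated per dataset with the precision module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .exceptions import ConfigurationError, InputError

SCORE_FLOOR = 1e-6  # floor inside log10; numerical safety far below threshold


@dataclass
class Spectrogram:
    times: np.ndarray   # frame centre times, s
    freqs: np.ndarray   # Hz
    power: np.ndarray   # (n_freq, n_frame), >= 0 before normalization
    window_s: float = 2.0
    overlap_frac: float = 0.8

    @property
    def dt(self) -> float:
        return self.window_s * (1.0 - self.overlap_frac)


@dataclass
class Kernel:
    lags: np.ndarray     # s, 0..duration
    freqs: np.ndarray    # Hz
    weights: np.ndarray  # (n_freq, n_lag), signed, zero sum
    center_freqs: np.ndarray = field(default=None)


@dataclass
class Detection:
    """One recognition-score peak on one station."""

    station_id: Optional[str]
    time: float          # UTC epoch seconds of the peak
    peak_rs: float       # peak recognition score (log10 scale)
    duration_s: float    # contiguous time above threshold around the peak
    p_true: Optional[float] = None  # filled by the precision module


@dataclass
class RecognitionSeries:
    times: np.ndarray
    values: np.ndarray
    dt: float


def spectrogram(waveform, fs: float, window_s: float = 2.0,
                overlap_frac: float = 0.8) -> Spectrogram:
    """Power spectrogram with a Hann window (default 2 s, 80% overlap)."""
    x = np.asarray(waveform, dtype=float)
    if fs < 40.0:
        raise InputError("sampling rate below 40 Hz; first harmonic must be below Nyquist")
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise InputError("record shorter than one spectrogram window")
    noverlap = int(round(overlap_frac * nperseg))
    f, t, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend=False, scaling="spectrum", mode="psd",
    )
    return Spectrogram(t, f, sxx, window_s, overlap_frac)


def median_normalize(spec: Spectrogram) -> Spectrogram:
    """Subtract the median at each frequency (row medians of the result are 0)."""
    if spec.power.shape[1] < 3:
        raise InputError("need at least 3 frames to median-normalize")
    med = np.median(spec.power, axis=1, keepdims=True)
    return Spectrogram(spec.times, spec.freqs, spec.power - med,
                       spec.window_s, spec.overlap_frac)


def build_kernel(f_start: float = 15.7, f_end: float = 14.4, dur: float = 10.0,
                 bandwidth: float = 0.5, dt: float = 0.4, df: float = 0.5,
                 f_pad: float = 2.5) -> Kernel:
    """Swept-tone detection kernel.

    At each lag the cross-frequency weight profile is the second derivative of
    a Gaussian centred on the instantaneous call frequency,
    ``w(f) ∝ (1 - z^2) exp(-z^2/2)`` with ``z = (f - f_c)/bandwidth`` and
    ``f_c`` sweeping linearly from f_start to f_end.  Column means are removed
    so the kernel sums to zero (the analytic profile already integrates to
    zero; the correction is at machine-precision level).
    """
    if f_start <= f_end:
        raise ConfigurationError("kernel must sweep downward (f_start > f_end)")
    if bandwidth <= 0:
        raise ConfigurationError("bandwidth must be positive")
    if df > bandwidth * (1 + 1e-9):
        raise ConfigurationError(
            f"frequency resolution {df} Hz too coarse to resolve bandwidth {bandwidth} Hz"
        )
    lags = np.arange(0.0, dur + dt / 2.0, dt)
    fc = f_start + (f_end - f_start) * lags / dur
    # Frequency rows on the df grid (multiples of df so they align with
    # spectrogram bins), padded to capture the negative side lobes.
    f_lo = np.floor((f_end - f_pad) / df) * df
    f_hi = np.ceil((f_start + f_pad) / df) * df
    freqs = np.arange(f_lo, f_hi + df / 2.0, df)
    z = (freqs[:, None] - fc[None, :]) / bandwidth
    w = (1.0 - z**2) * np.exp(-(z**2) / 2.0)
    w /= np.max(np.abs(w))
    w -= w.mean(axis=0, keepdims=True)
    return Kernel(lags, freqs, w, center_freqs=fc)


def recognition_score(spec: Spectrogram, kernel: Kernel, eps: float = SCORE_FLOOR,
                      scale_percentile: float = 90.0) -> RecognitionSeries:
    """log10 recognition-score series from the normalized spectrogram.

    The median-normalized spectrogram is rescaled so its scale_percentile
    value equals one, then correlated with the kernel with frequencies
    matched; the score at each start frame is log10 of the (floored) inner
    product over the kernel's 10-s window.
    """
    rows = []
    for f in kernel.freqs:
        idx = np.argmin(np.abs(spec.freqs - f))
        if abs(spec.freqs[idx] - f) > 1e-6:
            raise ConfigurationError(
                f"kernel frequency {f} Hz not present in spectrogram bins"
            )
        rows.append(idx)
    sub = spec.power[rows, :]
    scale = np.percentile(spec.power, scale_percentile)
    if scale > 0:
        sub = sub / scale
    n_lag = kernel.weights.shape[1]
    if sub.shape[1] < n_lag:
        raise InputError("spectrogram shorter than the kernel window")
    windows = sliding_window_view(sub, n_lag, axis=1)  # (n_freq, n_start, n_lag)
    lin = np.einsum("fl,ftl->t", kernel.weights, windows)
    rs = np.log10(np.maximum(eps, lin))
    return RecognitionSeries(spec.times[: rs.size], rs, spec.dt)


def pick_peaks(rs: RecognitionSeries, threshold: float = 2.2,
               min_sep_s: float = 10.0, station_id: Optional[str] = None,
               time_offset: float = 0.0) -> list:
    """Pick recognition-score peaks above threshold.

    A peak is retained only if no higher peak (retained or not) lies within
    min_sep_s of it; ties are broken in favour of the earlier peak.  Each
    detection records the peak time, peak score, and the contiguous duration
    above threshold around the peak.
    """
    v = np.asarray(rs.values, dtype=float)
    n = v.size
    cand = []
    for i in range(n):
        if v[i] <= threshold:
            continue
        left_ok = i == 0 or v[i] >= v[i - 1]
        right_ok = i == n - 1 or v[i] > v[i + 1]
        if left_ok and right_ok:
            cand.append(i)
    order = sorted(cand, key=lambda i: (-v[i], rs.times[i]))
    kept: list = []
    processed: list = []
    for i in order:
        if all(abs(rs.times[i] - rs.times[j]) >= min_sep_s for j in processed):
            kept.append(i)
        processed.append(i)
    out = []
    for i in sorted(kept, key=lambda i: rs.times[i]):
        lo = i
        while lo > 0 and v[lo - 1] > threshold:
            lo -= 1
        hi = i
        while hi < n - 1 and v[hi + 1] > threshold:
            hi += 1
        duration = (hi - lo + 1) * rs.dt
        out.append(Detection(station_id, float(rs.times[i] + time_offset),
                             float(v[i]), float(duration)))
    return out
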