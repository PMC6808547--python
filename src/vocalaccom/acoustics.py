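"""Per-call acoustic parameterization and call-selection rules.

Extracts the 15 (phee/food) or 17 (trill) per-call parameters used in the
dialect analyses: F0 contour statistics from a short-time autocorrelation
pitch tracker, spectral energy quartiles and peak frequency from the average
power spectrum, local jitter, call duration on an energy-envelope criterion,
and — for trills — the rate and depth of the periodic frequency modulation.

Also implements the data-inclusion rules: first-k call selection per
recording session with exclusion of flagged calls, and the
five-calls-per-week minimum for an animal to enter the weekly analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "CallWaveform",
    "F0Contour",
    "AcousticFeatures",
    "UnmeasurableCallError",
    "FEATURE_NAMES_COMMON",
    "FEATURE_NAMES_TRILL",
    "feature_names",
    "track_f0",
    "extract_features",
    "local_jitter",
    "energy_quartiles",
    "select_calls",
    "weekly_inclusion_filter",
    "read_wav",
    "write_wav",
]

#: the 15 parameters measured for every call type, in canonical CSV order
FEATURE_NAMES_COMMON = [
    "f0_start",
    "f0_end",
    "f0_mean",
    "f0_min",
    "f0_max",
    "pct_dur_f0max",
    "f0_abs_slope",
    "f0_var_per_s",
    "q1_freq",
    "q2_freq",
    "q3_freq",
    "peak_freq",
    "pct_time_peak_freq",
    "jitter",
    "duration",
]
#: trills additionally carry the two frequency-modulation parameters
FEATURE_NAMES_TRILL = FEATURE_NAMES_COMMON + ["fm_rate", "fm_extent"]


def feature_names(call_type: str) -> list[str]:
    return FEATURE_NAMES_TRILL if call_type == "trill" else FEATURE_NAMES_COMMON


class UnmeasurableCallError(ValueError):
    """Raised when a call cannot be measured (e.g. no voiced frames)."""


@dataclass
class CallWaveform:
    """One call's mono audio plus its recording metadata."""

    samples: np.ndarray
    sample_rate: int
    caller_id: str | None = None
    colony: str | None = None
    sex: str | None = None
    call_type: str | None = None
    condition: str | None = None
    week: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


@dataclass
class F0Contour:
    """Frame-wise fundamental-frequency track; NaN marks unvoiced frames."""

    times: np.ndarray  # frame centers, s, origin at call start
    f0: np.ndarray  # Hz, NaN where unvoiced
    step: float  # s

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)

    @property
    def n_voiced(self) -> int:
        return int(np.sum(self.voiced))

    @property
    def measurable(self) -> bool:
        return self.n_voiced >= 3


@dataclass
class AcousticFeatures:
    """The measured per-call parameters (trill-only fields None otherwise)."""

    f0_start: float
    f0_end: float
    f0_mean: float
    f0_min: float
    f0_max: float
    pct_dur_f0max: float
    f0_abs_slope: float
    f0_var_per_s: float
    q1_freq: float
    q2_freq: float
    q3_freq: float
    peak_freq: float
    pct_time_peak_freq: float
    jitter: float
    duration: float
    fm_rate: float | None = None
    fm_extent: float | None = None

    def as_vector(self, call_type: str) -> np.ndarray:
        names = feature_names(call_type)
        return np.array([getattr(self, n) for n in names], dtype=float)

    def as_dict(self, call_type: str) -> dict[str, float]:
        return {n: getattr(self, n) for n in feature_names(call_type)}


def _frame_signal(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """(n_frames, win) view of x; frames fully inside the signal."""
    n_frames = 1 + (len(x) - win) // hop
    if n_frames < 1:
        raise ValueError("signal shorter than one analysis frame")
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def track_f0(
    wave: CallWaveform,
    floor: float = 3000.0,
    ceiling: float = 14000.0,
    step: float = 0.005,
    window: float | None = None,
    voicing_threshold: float = 0.45,
    silence_threshold_db: float = -40.0,
) -> F0Contour:
    """Autocorrelation pitch tracking within [floor, ceiling].

    Each frame's normalized autocorrelation is peak-picked over candidate
    lags between 1/ceiling and 1/floor; the lag is refined by parabolic
    interpolation.  Frames whose normalized peak falls below
    ``voicing_threshold``, or whose RMS is more than ``silence_threshold_db``
    below the loudest frame, are marked unvoiced (NaN).

    The defaults (floor 3 kHz, ceiling 14 kHz, 5 ms step) bracket the tonal
    range of marmoset calls.
    """
    fs = wave.sample_rate
    if not (floor < ceiling < fs / 2):
        raise ValueError("need floor < ceiling < Nyquist")
    if window is None:
        window = 3.0 / floor
    lag_min = int(np.floor(fs / ceiling))
    lag_max = int(np.ceil(fs / floor))
    win = max(int(round(window * fs)), 2 * lag_max)
    hop = max(1, int(round(step * fs)))

    x = wave.samples - np.mean(wave.samples)
    if len(x) < win:
        x = np.pad(x, (0, win - len(x)))
    frames = _frame_signal(x, win, hop)
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * hop + win / 2) / fs

    rms = np.sqrt(np.mean(frames**2, axis=1))
    peak_rms = float(np.max(rms)) if n_frames else 0.0
    silence_floor = peak_rms * 10.0 ** (silence_threshold_db / 20.0)

    frames_c = frames - frames.mean(axis=1, keepdims=True)
    # Hann-windowed FFT autocorrelation of all frames at once; dividing by
    # the window's own autocorrelation deconvolves the taper (Boersma)
    hann = np.hanning(win)
    nfft = int(2 ** np.ceil(np.log2(2 * win)))
    spec = np.fft.rfft(frames_c * hann, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : lag_max + 2]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = np.inf
    # tapered normalized autocorrelation: the window taper penalizes
    # subharmonic (octave-down) candidates, so the peak is picked here ...
    acn_biased = ac / r0[:, None]
    # ... and refined on the deconvolved version, which has no taper-induced
    # shift of the peak location
    spec_w = np.fft.rfft(hann, nfft)
    ac_w = np.fft.irfft(spec_w * np.conj(spec_w), nfft)[: lag_max + 2]
    acn = acn_biased * (ac_w[0] / np.maximum(ac_w, 1e-12))[None, :]

    f0 = np.full(n_frames, np.nan)
    for i in range(n_frames):
        if rms[i] <= silence_floor or peak_rms == 0.0:
            continue
        seg = acn_biased[i, lag_min : lag_max + 1]
        j = int(np.argmax(seg))
        lag = lag_min + j
        # walk uphill on the deconvolved curve (taper can shift the integer
        # peak by one sample)
        while lag + 1 <= lag_max and acn[i, lag + 1] > acn[i, lag]:
            lag += 1
        while lag - 1 >= lag_min and acn[i, lag - 1] > acn[i, lag]:
            lag -= 1
        if acn[i, lag] < voicing_threshold:
            continue
        # refine around the peak (unbiased curve): exact for a cosine-shaped
        # peak, falling back to parabolic interpolation otherwise
        delta = 0.0
        if 0 < lag < lag_max + 1:
            y0, y1, y2 = acn[i, lag - 1], acn[i, lag], acn[i, lag + 1]
            cosw = (y0 + y2) / (2 * y1) if y1 != 0 else np.nan
            if np.isfinite(cosw) and -1.0 < cosw < 1.0:
                w_loc = np.arccos(cosw)
                theta = np.arctan2((y2 - y0) / (2 * np.sin(w_loc)), y1)
                delta = float(np.clip(theta / w_loc, -0.5, 0.5))
            else:
                denom = y0 - 2 * y1 + y2
                if denom != 0:
                    delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
        cand = fs / (lag + delta)
        if floor <= cand <= ceiling:
            f0[i] = cand
    return F0Contour(times=times, f0=f0, step=hop / fs)


def local_jitter(periods: np.ndarray) -> float:
    """Cycle-to-cycle period perturbation, %.

    Mean absolute difference of consecutive periods divided by the mean
    period, times 100.
    """
    periods = np.asarray(periods, dtype=float)
    if periods.size < 2:
        raise UnmeasurableCallError("jitter needs at least 2 period estimates")
    return float(np.mean(np.abs(np.diff(periods))) / np.mean(periods) * 100.0)


def energy_quartiles(samples: np.ndarray, sample_rate: float) -> tuple[float, float, float]:
    """Frequencies at 25/50/75% of cumulative spectral energy (Welch PSD)."""
    x = np.asarray(samples, dtype=float)
    nper = min(len(x), 1024)
    freqs, psd = signal.welch(x, fs=sample_rate, nperseg=nper)
    cum = np.cumsum(psd)
    if cum[-1] <= 0:
        raise UnmeasurableCallError("zero spectral energy")
    return tuple(
        float(freqs[int(np.searchsorted(cum, q * cum[-1]))]) for q in (0.25, 0.5, 0.75)
    )


def _duration_from_envelope(
    x: np.ndarray, fs: float, threshold_db: float = -25.0, step: float = 0.005
) -> float:
    """Call duration on a −25 dB energy-envelope threshold, half-open frames."""
    hop = max(1, int(round(step * fs)))
    win = hop
    n_frames = max(1, len(x) // hop)
    seg = x[: n_frames * hop].reshape(n_frames, win)
    rms = np.sqrt(np.mean(seg**2, axis=1))
    peak = float(np.max(rms))
    if peak == 0:
        return 0.0
    above = np.nonzero(rms >= peak * 10.0 ** (threshold_db / 20.0))[0]
    return float((above[-1] + 1 - above[0]) * hop / fs)


def _fm_parameters(
    contour: F0Contour, method: str = "sinefit", min_rate: float = 2.0
) -> tuple[float, float]:
    """FM rate (Hz) and peak-to-trough extent (Hz) of the F0 contour.

    The rate is the dominant frequency of the mean-removed contour spectrum
    (zero-padded periodogram with parabolic peak interpolation).  The extent
    is, by default, twice the amplitude of a least-squares sinusoid fitted at
    that rate — i.e. the peak-to-trough excursion of the underlying
    modulation, robust to the coarse contour sampling.  ``method="peaks"``
    instead averages the raw sample-level peak-to-trough differences.
    """
    voiced = contour.voiced
    t = contour.times[voiced]
    v = contour.f0[voiced]
    if v.size < 8:
        raise UnmeasurableCallError("too few voiced frames for FM analysis")
    # resample onto the uniform frame grid (interpolate across unvoiced gaps)
    tt = contour.times[(contour.times >= t[0]) & (contour.times <= t[-1])]
    vv = np.interp(tt, t, v)
    vv = vv - np.mean(vv)
    fs_c = 1.0 / contour.step
    nfft = max(8192, int(2 ** np.ceil(np.log2(vv.size * 4))))
    spec = np.abs(np.fft.rfft(vv * np.hanning(vv.size), nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, contour.step)
    valid = freqs >= min_rate
    if not np.any(valid):
        raise UnmeasurableCallError("contour too short to resolve FM")
    k0 = int(np.argmax(np.where(valid, spec, -np.inf)))
    if 0 < k0 < spec.size - 1:
        y0, y1, y2 = spec[k0 - 1], spec[k0], spec[k0 + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    rate = float((k0 + delta) * fs_c / nfft)

    if method == "sinefit":
        w = 2 * np.pi * rate
        design = np.column_stack([np.sin(w * tt), np.cos(w * tt), np.ones_like(tt)])
        coef, *_ = np.linalg.lstsq(design, vv, rcond=None)
        extent = 2.0 * float(np.hypot(coef[0], coef[1]))
    elif method == "peaks":
        peaks, _ = signal.find_peaks(vv)
        troughs, _ = signal.find_peaks(-vv)
        if peaks.size == 0 or troughs.size == 0:
            raise UnmeasurableCallError("no FM peaks found")
        extent = float(np.mean(vv[peaks]) - np.mean(vv[troughs]))
    else:
        raise ValueError(f"unknown fm method {method!r}")
    return rate, extent


def extract_features(
    wave: CallWaveform,
    contour: F0Contour | None = None,
    *,
    floor: float = 3000.0,
    ceiling: float = 14000.0,
    f0_tolerance: float = 0.01,
    fm_method: str = "sinefit",
) -> AcousticFeatures:
    """Compute the full per-call parameter vector.

    F0 statistics come from the voiced frames of the contour; spectral
    measures from the call's average power spectrum (Welch); jitter from the
    frame-wise period sequence; duration from a −25 dB energy envelope.
    Raises :class:`UnmeasurableCallError` when fewer than 3 voiced frames
    exist.
    """
    if contour is None:
        contour = track_f0(wave, floor=floor, ceiling=ceiling)
    if not contour.measurable:
        raise UnmeasurableCallError("call has fewer than 3 voiced frames")
    voiced = contour.f0[contour.voiced]
    dur = _duration_from_envelope(wave.samples, wave.sample_rate)
    if dur <= 0:
        raise UnmeasurableCallError("no energy above the envelope threshold")

    f0_start = float(voiced[0])
    f0_end = float(voiced[-1])
    f0_mean = float(np.mean(voiced))
    f0_min = float(np.min(voiced))
    f0_max = float(np.max(voiced))
    pct_dur_f0max = float(np.mean(voiced >= f0_max * (1 - f0_tolerance)) * 100.0)
    f0_abs_slope = abs(f0_end - f0_start) / dur
    f0_var_per_s = float(np.mean(np.abs(np.diff(voiced))) / contour.step) if voiced.size > 1 else 0.0
    jitter = local_jitter(1.0 / voiced)

    # average power spectrum of the whole call
    x = wave.samples
    nper = min(len(x), 1024)
    q1, q2, q3 = energy_quartiles(x, wave.sample_rate)
    freqs, psd = signal.welch(x, fs=wave.sample_rate, nperseg=nper)
    peak_freq = float(freqs[int(np.argmax(psd))])

    # fraction of frames whose own spectral peak sits at the overall peak
    f_s, _, sxx = signal.spectrogram(x, fs=wave.sample_rate, nperseg=nper, noverlap=nper // 2)
    frame_peaks = f_s[np.argmax(sxx, axis=0)]
    pct_time_peak = float(np.mean(np.abs(frame_peaks - peak_freq) <= f0_tolerance * max(peak_freq, 1.0)) * 100.0)

    fm_rate = fm_extent = None
    if wave.call_type == "trill":
        fm_rate, fm_extent = _fm_parameters(contour, method=fm_method)

    return AcousticFeatures(
        f0_start=f0_start,
        f0_end=f0_end,
        f0_mean=f0_mean,
        f0_min=f0_min,
        f0_max=f0_max,
        pct_dur_f0max=pct_dur_f0max,
        f0_abs_slope=f0_abs_slope,
        f0_var_per_s=f0_var_per_s,
        q1_freq=q1,
        q2_freq=q2,
        q3_freq=q3,
        peak_freq=peak_freq,
        pct_time_peak_freq=pct_time_peak,
        jitter=jitter,
        duration=dur,
        fm_rate=fm_rate,
        fm_extent=fm_extent,
    )


DEFAULT_QUOTAS = {"phee": 10, "trill": 5, "food": 20}


def select_calls(
    calls: pd.DataFrame,
    quotas: dict[str, int] | None = None,
    *,
    session_col: str = "session",
    call_type_col: str = "call_type",
    exclude_col: str = "excluded",
) -> pd.DataFrame:
    """First-k call selection per session and call type.

    Calls flagged in ``exclude_col`` (overlapping / noisy / unmeasurable) are
    dropped first; then the first ``quota`` calls of each type are kept in
    chronological (row) order.  Sessions with fewer clean calls than the
    quota keep everything they have.
    """
    quotas = DEFAULT_QUOTAS if quotas is None else quotas
    df = calls
    if exclude_col in df.columns:
        df = df[~df[exclude_col].astype(bool)]
    out = []
    for (_, ct), grp in df.groupby([session_col, call_type_col], sort=False):
        k = quotas.get(ct)
        out.append(grp if k is None else grp.head(k))
    if not out:
        return df.iloc[0:0]
    return pd.concat(out).sort_index()


def weekly_inclusion_filter(
    table: pd.DataFrame,
    min_calls: int = 5,
    *,
    caller_col: str = "caller_id",
    call_type_col: str = "call_type",
    week_col: str = "week",
) -> pd.DataFrame:
    """Drop (caller, call type, week) cells contributing fewer than 5 calls."""
    counts = table.groupby([caller_col, call_type_col, week_col])[caller_col].transform("size")
    return table[counts >= min_calls]


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono RIFF WAV as float64 in [-1, 1]."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected mono WAV")
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    else:
        data = data.astype(float)
    return data, int(fs)


def write_wav(path, samples: np.ndarray, sample_rate: int) -> None:
    """Write 16-bit PCM mono RIFF WAV."""
    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (x * 32767).astype(np.int16))
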