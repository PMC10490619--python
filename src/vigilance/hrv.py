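"""ECG -> heart-rate-variability features.

The chain is: zero-phase band-pass filtering, Pan-Tompkins R-wave detection,
RR-series construction with median-based artifact correction, and the 14
standard HRV features (time domain, Lomb-Scargle frequency domain, Poincare
and entropy measures).

Conventions fixed here (and relied on by the tests):

* SDRR and every other standard deviation uses the sample (n-1) estimator.
* The Lomb-Scargle PSD is normalized so that the 0-0.4 Hz integral equals the
  sample variance of the tachogram (ms^2); band powers are therefore in ms^2.
* Entropy tolerance r defaults to 0.2 * SD(series) (n-1), frozen once per
  series and shared by ApEn and SampEn.
* ApEn counts self-matches, SampEn excludes them; SampEn's B statistic uses
  all N-m+1 length-m templates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidArgumentError,
)

__all__ = [
    "ECGRecording",
    "RRSeries",
    "PSDEstimate",
    "HRVFeatureVector",
    "EntropyParams",
    "HRV_FEATURE_NAMES",
    "bandpass_filter",
    "detect_r_peaks",
    "build_rr_series",
    "time_domain_features",
    "lomb_scargle_psd",
    "frequency_domain_features",
    "poincare_features",
    "approximate_entropy",
    "sample_entropy",
    "extract_hrv",
    "features_from_rr",
]

#: canonical column order for feature tables (time, frequency, nonlinear)
HRV_FEATURE_NAMES = [
    "mRR",
    "SDRR",
    "RMSSD",
    "pNN50",
    "VLF",
    "LF",
    "HF",
    "TP",
    "LF_HF",
    "nLF",
    "nHF",
    "SD_ratio",
    "ApEn",
    "SampEn",
]

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass
class ECGRecording:
    """Single-channel ECG trace in millivolts."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        if self.samples.size < 2 * self.fs:
            raise InsufficientDataError("ECG recording must span at least 2 s")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class RRSeries:
    """Inter-beat intervals derived from R-peak instants.

    ``intervals[i] == (peak_times[i+1] - peak_times[i]) * 1000`` unless the
    interval was flagged as artifactual and replaced by interpolation.
    """

    peak_times: np.ndarray  # s, strictly increasing
    intervals: np.ndarray  # ms
    artifact_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.intervals.size, dtype=bool)
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if np.any(np.diff(self.peak_times) <= 0):
            raise InvalidArgumentError("peak times must be strictly increasing")
        if np.any(self.intervals <= 0):
            raise InvalidArgumentError("RR intervals must be positive")

    @classmethod
    def from_peaks(cls, peak_times: np.ndarray) -> "RRSeries":
        peak_times = np.asarray(peak_times, dtype=float)
        return cls(peak_times, np.diff(peak_times) * 1000.0)

    @property
    def interval_times(self) -> np.ndarray:
        """Time stamp of each interval = instant of its closing R peak."""
        return self.peak_times[1:]

    def __len__(self) -> int:
        return self.intervals.size


@dataclass
class PSDEstimate:
    frequencies: np.ndarray  # Hz, covers 0-0.4
    power: np.ndarray  # ms^2/Hz, nonnegative

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)


@dataclass
class HRVFeatureVector:
    mRR: float
    SDRR: float
    RMSSD: float
    pNN50: float
    VLF: float
    LF: float
    HF: float
    TP: float
    LF_HF: float
    nLF: float
    nHF: float
    SD_ratio: float  # SD1/SD2
    ApEn: float
    SampEn: float
    sd1: float = float("nan")
    sd2: float = float("nan")

    @property
    def sd2_sd1(self) -> float:
        """Inverse Poincare ratio (SD2/SD1)."""
        return 1.0 / self.SD_ratio

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in HRV_FEATURE_NAMES}


@dataclass
class EntropyParams:
    m: int = 2
    r: float | None = None  # None -> resolved to 0.2*SD of the series

    def resolve_r(self, series: np.ndarray) -> float:
        if self.r is not None:
            return float(self.r)
        return 0.2 * float(np.std(series, ddof=1))


# ---------------------------------------------------------------------------
# filtering & detection
# ---------------------------------------------------------------------------


def bandpass_filter(ecg: ECGRecording, low: float, high: float, order: int = 4) -> ECGRecording:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    if not (0 < low < high < ecg.fs / 2):
        raise InvalidArgumentError(
            f"band ({low}, {high}) Hz invalid for fs={ecg.fs} Hz"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=ecg.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, ecg.samples)
    return ECGRecording(filtered, ecg.fs, ecg.start_time)


def _moving_window_integrate(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(
    ecg: ECGRecording,
    refractory: float = 0.2,
    integration_window: float = 0.15,
) -> np.ndarray:
    """Pan-Tompkins R-wave detection.

    Band-pass (5-15 Hz) -> five-point derivative -> squaring -> moving-window
    integration -> adaptive dual thresholds with search-back and a 200 ms
    refractory period. Accepted detections are refined to the local extremum
    of the band-passed signal so peak instants land on the R wave itself.

    Returns peak times in seconds (empty array for flat/silent input).
    """
    if ecg.duration < 5.0:
        raise InsufficientDataError("Pan-Tompkins needs at least 5 s of signal")
    fs = ecg.fs
    x = ecg.samples - np.mean(ecg.samples)
    if np.ptp(x) == 0:
        return np.array([])

    bp = bandpass_filter(ECGRecording(x, fs), 5.0, min(15.0, fs / 2 - 1e-6)).samples
    # classic five-point derivative
    deriv = sps.lfilter(np.array([1, 2, 0, -2, -1]) * (fs / 8.0), [1.0], bp)
    squared = deriv**2
    mwi = _moving_window_integrate(squared, max(1, int(round(integration_window * fs))))

    min_dist = max(1, int(round(refractory * fs)))
    cand_idx, _ = sps.find_peaks(mwi, distance=min_dist)
    if cand_idx.size == 0:
        return np.array([])

    # adaptive dual-threshold state machine over candidate peaks only
    train = mwi[: int(2 * fs)]
    spki = float(np.max(train)) * 0.25 if train.size else float(mwi[cand_idx[0]])
    npki = float(np.mean(train)) * 0.5 if train.size else 0.0
    thr1 = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_history: list[float] = []
    noise_buffer: list[int] = []

    def _accept(idx: int, level: float) -> None:
        nonlocal spki
        accepted.append(idx)
        spki = 0.125 * level + 0.875 * spki

    for idx in cand_idx:
        level = float(mwi[idx])
        if level > thr1:
            _accept(idx, level)
            noise_buffer.clear()
        else:
            npki = 0.125 * level + 0.875 * npki
            noise_buffer.append(idx)
        # search-back: expected beat missed -> revisit noise peaks above THR2
        if len(accepted) >= 2:
            rr_history.append(float(accepted[-1] - accepted[-2]))
            if len(rr_history) > 8:
                rr_history.pop(0)
        if rr_history and accepted:
            mean_rr = float(np.mean(rr_history))
            if (idx - accepted[-1]) > 1.66 * mean_rr and noise_buffer:
                thr2 = npki + 0.125 * (spki - npki)
                back = [j for j in noise_buffer if mwi[j] > thr2 and j - accepted[-1] >= min_dist]
                if back:
                    best = max(back, key=lambda j: mwi[j])
                    _accept(best, float(mwi[best]))
                    accepted.sort()
                    noise_buffer.clear()
        thr1 = npki + 0.25 * (spki - npki)

    if not accepted:
        return np.array([])

    # refine to the R wave: local maximum of the raw signal in a window
    # ending at the MWI peak (integration delays the energy peak past R)
    half = int(round(integration_window * fs))
    refined = []
    for idx in accepted:
        lo = max(0, idx - half)
        hi = min(x.size, idx + half // 2 + 1)
        window = x[lo:hi] - np.median(x[lo:hi])  # remove local baseline
        refined.append(lo + int(np.argmax(window)))
    refined_arr = np.unique(np.asarray(refined))
    # enforce refractory after refinement
    keep = [int(refined_arr[0])]
    for idx in refined_arr[1:]:
        if idx - keep[-1] >= min_dist:
            keep.append(int(idx))
        elif x[idx] > x[keep[-1]]:
            keep[-1] = int(idx)

    # sub-sample refinement: parabola through the three samples around each
    # peak (timing precision beyond the sampling grid)
    times = []
    for idx in keep:
        offset = 0.0
        if 0 < idx < x.size - 1:
            denom = x[idx - 1] - 2 * x[idx] + x[idx + 1]
            if denom < 0:
                offset = float(np.clip(0.5 * (x[idx - 1] - x[idx + 1]) / denom, -0.5, 0.5))
        times.append((idx + offset) / fs)
    return ecg.start_time + np.asarray(times)


# ---------------------------------------------------------------------------
# RR construction
# ---------------------------------------------------------------------------


def build_rr_series(
    peak_times: np.ndarray,
    correction_threshold: float = 0.3,
    neighborhood: int = 11,
) -> RRSeries:
    """Construct an RR series and correct artifactual intervals.

    An interval deviating more than ``correction_threshold`` (fraction) from
    the median of its ``neighborhood`` surrounding intervals is flagged and
    replaced by cubic interpolation through the unflagged intervals.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 3:
        raise InsufficientDataError("need at least 3 peaks to build an RR series")
    intervals = np.diff(peak_times) * 1000.0
    local_med = median_filter(intervals, size=neighborhood, mode="nearest")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_dev = np.abs(intervals - local_med) / local_med
    flags = rel_dev > correction_threshold

    corrected = intervals.copy()
    if flags.any() and (~flags).sum() >= 2:
        good = np.flatnonzero(~flags)
        bad = np.flatnonzero(flags)
        if good.size >= 4:
            spline = CubicSpline(good, intervals[good])
            corrected[bad] = spline(bad)
        else:
            corrected[bad] = np.interp(bad, good, intervals[good])
    return RRSeries(peak_times, corrected, flags)


# ---------------------------------------------------------------------------
# time-domain features
# ---------------------------------------------------------------------------


def time_domain_features(rr: RRSeries) -> tuple[float, float, float, float]:
    """(mRR, SDRR, RMSSD, pNN50): mean, sample SD, RMS of successive
    differences, and the percentage of successive differences above 50 ms."""
    x = rr.intervals
    if x.size < 2:
        raise InsufficientDataError("need at least 2 intervals")
    d = np.diff(x)
    mrr = float(np.mean(x))
    sdrr = float(np.std(x, ddof=1))
    rmssd = float(np.sqrt(np.mean(d**2)))
    pnn50 = float(100.0 * np.count_nonzero(np.abs(d) > 50.0) / d.size)
    return mrr, sdrr, rmssd, pnn50


# ---------------------------------------------------------------------------
# frequency-domain features
# ---------------------------------------------------------------------------


def lomb_scargle_psd(
    rr: RRSeries,
    grid_step: float = 0.002,
    f_max: float = 0.4,
) -> PSDEstimate:
    """Lomb-Scargle PSD of the (time, interval) tachogram on a uniform grid.

    The raw periodogram is rescaled so that its trapezoidal integral over
    0-``f_max`` equals the sample variance of the intervals; band integrals
    are then absolute powers in ms^2.
    """
    if len(rr) < 16:
        raise InsufficientDataError("need at least 16 intervals for spectral analysis")
    if grid_step <= 0 or grid_step > 0.005:
        raise InvalidArgumentError("grid_step must be in (0, 0.005] Hz")
    t = rr.interval_times
    x = rr.intervals - np.mean(rr.intervals)
    freqs = np.arange(grid_step, f_max + grid_step / 2, grid_step)
    pgram = sps.lombscargle(t, x, 2 * np.pi * freqs)
    # extend flat down to DC so the grid covers 0 Hz
    freqs = np.concatenate(([0.0], freqs))
    pgram = np.concatenate(([pgram[0]], pgram))
    pgram = np.maximum(pgram, 0.0)
    var = float(np.var(x, ddof=1))
    raw_integral = float(np.trapezoid(pgram, freqs))
    scale = var / raw_integral if raw_integral > 0 else 0.0
    return PSDEstimate(freqs, pgram * scale)


def _band_power(psd: PSDEstimate, lo: float, hi: float) -> float:
    """Trapezoidal integral over [lo, hi] with interpolated band edges."""
    f, p = psd.frequencies, psd.power
    inner = (f > lo) & (f < hi)
    grid = np.concatenate(([lo], f[inner], [hi]))
    vals = np.concatenate(
        ([np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)])
    )
    return float(np.trapezoid(vals, grid))


def frequency_domain_features(
    psd: PSDEstimate,
) -> tuple[float, float, float, float, float, float, float]:
    """(VLF, LF, HF, TP, LF_HF, nLF, nHF) from band integrals of the PSD."""
    if psd.frequencies[0] > 0 or psd.frequencies[-1] < HF_BAND[1] - 1e-12:
        raise InvalidArgumentError("PSD grid must cover 0-0.4 Hz")
    vlf = _band_power(psd, *VLF_BAND)
    lf = _band_power(psd, *LF_BAND)
    hf = _band_power(psd, *HF_BAND)
    tp = vlf + lf + hf
    if hf == 0.0:
        warnings.warn("HF power is zero; LF/HF reported as +inf", stacklevel=2)
        lf_hf = float("inf")
    else:
        lf_hf = lf / hf
    denom = lf + hf
    if denom == 0.0:
        nlf = nhf = float("nan")
    else:
        nlf = 100.0 * lf / denom
        nhf = 100.0 - nlf
    return vlf, lf, hf, tp, lf_hf, nlf, nhf


# ---------------------------------------------------------------------------
# nonlinear features
# ---------------------------------------------------------------------------


def poincare_features(rr: RRSeries) -> tuple[float, float, float]:
    """(SD1, SD2, SD1/SD2) of the Poincare plot, all with (n-1) scaling."""
    x = rr.intervals
    if x.size < 3:
        raise InsufficientDataError("need at least 3 intervals")
    d = np.diff(x)
    sd1 = float(np.sqrt(0.5 * np.var(d, ddof=1)))
    sdrr = float(np.std(x, ddof=1))
    sd2_sq = 2.0 * sdrr**2 - sd1**2
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    if sd2 == 0.0:
        raise DegenerateInputError("SD2 is zero; Poincare ratio undefined")
    return sd1, sd2, sd1 / sd2


def _template_matrix(x: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)


def _apen_phi(x: np.ndarray, m: int, r: float) -> float:
    templates = _template_matrix(x, m)
    n_templ = templates.shape[0]
    dist = np.max(np.abs(templates[:, None, :] - templates[None, :, :]), axis=2)
    counts = np.count_nonzero(dist <= r, axis=1)
    return float(np.mean(np.log(counts / n_templ)))


def approximate_entropy(series: np.ndarray, params: EntropyParams | None = None) -> float:
    """ApEn(m, r) with self-matches included (Pincus formulation)."""
    params = params or EntropyParams()
    x = np.asarray(series, dtype=float)
    if x.size < params.m + 2:
        raise InsufficientDataError("series too short for the embedding dimension")
    r = params.resolve_r(x)
    if r <= 0:
        raise InvalidArgumentError("tolerance r must be positive")
    return _apen_phi(x, params.m, r) - _apen_phi(x, params.m + 1, r)


def _pair_count(x: np.ndarray, m: int, r: float) -> int:
    templates = _template_matrix(x, m)
    dist = np.max(np.abs(templates[:, None, :] - templates[None, :, :]), axis=2)
    within = dist <= r
    return int((np.count_nonzero(within) - templates.shape[0]) // 2)


def sample_entropy(series: np.ndarray, params: EntropyParams | None = None) -> float:
    """SampEn(m, r) = -ln(A/B); self-matches excluded.

    B counts matching pairs among all N-m+1 length-m templates, A among the
    N-m length-(m+1) templates. Returns NaN (with a warning) when either
    count is zero.
    """
    params = params or EntropyParams()
    x = np.asarray(series, dtype=float)
    if x.size < params.m + 2:
        raise InsufficientDataError("series too short for the embedding dimension")
    r = params.resolve_r(x)
    if r <= 0:
        raise InvalidArgumentError("tolerance r must be positive")
    b = _pair_count(x, params.m, r)
    a = _pair_count(x, params.m + 1, r)
    if a == 0 or b == 0:
        warnings.warn("no matching templates; SampEn undefined", stacklevel=2)
        return float("nan")
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def features_from_rr(
    rr: RRSeries,
    grid_step: float = 0.002,
    entropy: EntropyParams | None = None,
) -> HRVFeatureVector:
    """All 14 HRV features from an RR series (detection already done)."""
    entropy = entropy or EntropyParams()
    mrr, sdrr, rmssd, pnn50 = time_domain_features(rr)
    psd = lomb_scargle_psd(rr, grid_step=grid_step)
    vlf, lf, hf, tp, lf_hf, nlf, nhf = frequency_domain_features(psd)
    sd1, sd2, sd_ratio = poincare_features(rr)
    r = entropy.resolve_r(rr.intervals)
    frozen = EntropyParams(m=entropy.m, r=r)
    apen = approximate_entropy(rr.intervals, frozen)
    sampen = sample_entropy(rr.intervals, frozen)
    return HRVFeatureVector(
        mRR=mrr, SDRR=sdrr, RMSSD=rmssd, pNN50=pnn50,
        VLF=vlf, LF=lf, HF=hf, TP=tp, LF_HF=lf_hf, nLF=nlf, nHF=nhf,
        SD_ratio=sd_ratio, ApEn=apen, SampEn=sampen, sd1=sd1, sd2=sd2,
    )


def extract_hrv(
    ecg: ECGRecording,
    correction_threshold: float = 0.3,
    grid_step: float = 0.002,
    entropy: EntropyParams | None = None,
) -> HRVFeatureVector:
    """Full chain: detect R peaks, build the RR series, compute all features."""
    if ecg.duration < 60.0:
        raise InsufficientDataError("HRV extraction needs at least 60 s of ECG")
    peaks = detect_r_peaks(ecg)
    if peaks.size < 3:
        raise InsufficientDataError("too few detected R peaks")
    rr = build_rr_series(peaks, correction_threshold=correction_threshold)
    return features_from_rr(rr, grid_step=grid_step, entropy=entropy)
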