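"""Spectrogram computation and per-segment acoustic measurement.

Measures, for each labelled call segment, the 14 parameters used
throughout the analysis: duration, -20 dB bandwidth and min/max
frequency, mean F0 and the onset/offset F0 transitions, mean-spectrum
peak frequency, and the 25/50/75% energy quartiles computed both from
the mean spectrum and from the maximum-amplitude frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

#: the 14 measured parameters, in reporting order
FEATURE_COLUMNS = [
    "duration",
    "bandwidth_mean",
    "f0_mean",
    "onset",
    "offset",
    "max_freq",
    "min_freq",
    "peak_frequency_mean",
    "q25_mean",
    "q50_mean",
    "q75_mean",
    "q25_max",
    "q50_max",
    "q75_max",
]

FACTOR_COLUMNS = ["individual_id", "group_id", "sex", "context"]

SEGMENT_KINDS = ("whole", "noisy", "harmonic")


@dataclass(frozen=True)
class SpectrogramParams:
    """Analysis FFT settings (1,024-point Hamming, 96.87% overlap)."""

    sample_rate: float
    fft_size: int = 1024
    window: str = "hamming"
    overlap_fraction: float = 0.9687

    def __post_init__(self) -> None:
        if not (self.fft_size > 0 and (self.fft_size & (self.fft_size - 1)) == 0):
            raise ValueError(f"fft_size must be a positive power of two, "
                             f"got {self.fft_size}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.hop < 1:
            raise ValueError("overlap too high: hop < 1 sample")

    @property
    def bin_width(self) -> float:
        """Frequency resolution in Hz (sample_rate / fft_size)."""
        return self.sample_rate / self.fft_size

    @property
    def hop(self) -> int:
        """Frame advance in samples."""
        return int(round(self.fft_size * (1.0 - self.overlap_fraction)))


@dataclass
class Spectrogram:
    power: np.ndarray          # (n_frames, n_bins), >= 0
    times: np.ndarray          # frame centre times, s
    freqs: np.ndarray          # bin centre frequencies, Hz
    params: SpectrogramParams


@dataclass
class F0Track:
    times: np.ndarray
    f0: np.ndarray             # Hz; NaN where unvoiced

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)


@dataclass
class SegmentFeatures:
    duration: float
    bandwidth_mean: float
    f0_mean: float
    onset: float
    offset: float
    max_freq: float
    min_freq: float
    peak_frequency_mean: float
    q25_mean: float
    q50_mean: float
    q75_mean: float
    q25_max: float
    q50_max: float
    q75_max: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_COLUMNS}


def compute_spectrogram(waveform: np.ndarray,
                        params: SpectrogramParams) -> Spectrogram:
    """Short-time power spectrum with the configured window and overlap."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("waveform must be one-dimensional")
    if waveform.size < params.fft_size:
        raise ValueError(f"waveform of {waveform.size} samples is shorter than "
                         f"one {params.fft_size}-sample analysis window")
    freqs, times, sxx = signal.spectrogram(
        waveform, fs=params.sample_rate, window=params.window,
        nperseg=params.fft_size, noverlap=params.fft_size - params.hop,
        detrend=False, mode="psd")
    return Spectrogram(power=sxx.T, times=times, freqs=freqs, params=params)


def _quartile_freqs(spectrum: np.ndarray, freqs: np.ndarray,
                    fractions=(0.25, 0.50, 0.75)) -> tuple[float, ...]:
    """Frequencies below which the given fractions of spectral energy lie.

    Linear interpolation inside the crossing bin removes bin-width
    quantization.
    """
    cum = np.cumsum(spectrum, dtype=float)
    total = cum[-1]
    if total <= 0:
        raise ValueError("segment has no spectral energy")
    out = []
    for frac in fractions:
        target = frac * total
        i = int(np.searchsorted(cum, target))
        i = min(i, len(cum) - 1)
        lo_cum = cum[i - 1] if i > 0 else 0.0
        lo_f = freqs[i - 1] if i > 0 else 0.0
        span = cum[i] - lo_cum
        t = (target - lo_cum) / span if span > 0 else 0.0
        out.append(float(lo_f + t * (freqs[i] - lo_f)))
    return tuple(out)


def _band_edges(spectrum: np.ndarray, freqs: np.ndarray,
                threshold_db: float = -20.0) -> tuple[float, float]:
    """Lowest/highest frequency whose power exceeds peak + threshold_db."""
    peak = float(np.max(spectrum))
    if peak <= 0:
        raise ValueError("segment has no spectral energy")
    thr = peak * 10.0 ** (threshold_db / 10.0)
    above = np.nonzero(spectrum > thr)[0]
    return float(freqs[above[0]]), float(freqs[above[-1]])


def estimate_f0(segment: np.ndarray, sample_rate: float,
                search_range: tuple[float, float] = (100.0, 1000.0),
                frame_duration: float = 0.030, hop_duration: float = 0.010,
                voicing_threshold: float = 0.3) -> F0Track:
    """Frame-wise F0 by normalized autocorrelation with parabolic refinement.

    Within each frame, candidate lags are local autocorrelation maxima in
    the search band; the smallest lag within 15% of the global maximum is
    chosen, which suppresses octave-down errors on harmonic stacks.
    Frames whose peak falls below ``voicing_threshold`` are NaN.
    """
    x = np.asarray(segment, dtype=float)
    fmin, fmax = search_range
    min_len = int(np.ceil(2 * sample_rate / fmin))
    if x.size < min_len:
        raise ValueError(f"segment of {x.size} samples is shorter than two "
                         f"periods of {fmin} Hz ({min_len} samples)")
    frame_len = min(int(round(frame_duration * sample_rate)), x.size)
    frame_len = max(frame_len, min_len)
    hop = max(1, int(round(hop_duration * sample_rate)))

    starts = list(range(0, x.size - frame_len + 1, hop))
    if starts[-1] != x.size - frame_len:
        starts.append(x.size - frame_len)   # last frame flush with segment end

    lag_min = max(2, int(np.floor(sample_rate / fmax)))
    lag_max = min(int(np.ceil(sample_rate / fmin)), frame_len - 2)

    times = np.empty(len(starts))
    f0 = np.full(len(starts), np.nan)
    for idx, s in enumerate(starts):
        frame = x[s:s + frame_len] - np.mean(x[s:s + frame_len])
        times[idx] = (s + frame_len / 2) / sample_rate
        energy = np.sum(frame**2)
        if energy <= 0:
            continue
        # FFT autocorrelation, normalized per lag
        nfft = int(2 ** np.ceil(np.log2(2 * frame_len)))
        spec = np.fft.rfft(frame, nfft)
        ac = np.fft.irfft(spec * np.conj(spec))[:frame_len]
        sq = np.cumsum(frame**2)
        # norm(tau) = sqrt(sum x[:-tau]^2 * sum x[tau:]^2)
        lags = np.arange(lag_min, lag_max + 1)
        head = sq[frame_len - lags - 1]
        tail = sq[-1] - sq[lags - 1]
        norm = np.sqrt(head * tail)
        r = np.where(norm > 0, ac[lags] / norm, 0.0)

        peaks = np.nonzero((r[1:-1] >= r[:-2]) & (r[1:-1] >= r[2:]) &
                           (r[1:-1] >= voicing_threshold))[0] + 1
        if peaks.size == 0:
            continue
        best = float(np.max(r[peaks]))
        chosen = peaks[np.nonzero(r[peaks] >= best - 0.15 * abs(best))[0][0]]
        lag = float(lags[chosen])
        if 0 < chosen < len(r) - 1:   # parabolic interpolation
            y0, y1, y2 = r[chosen - 1], r[chosen], r[chosen + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                lag += 0.5 * (y0 - y2) / denom
        est = sample_rate / lag
        if fmin <= est <= fmax:
            f0[idx] = est
    return F0Track(times=times, f0=f0)


def _f0_features(segment: np.ndarray, sample_rate: float,
                 **f0_kwargs) -> tuple[float, float, float]:
    """(f0_mean, onset, offset); NaN triple when unvoiced or too short."""
    try:
        track = estimate_f0(segment, sample_rate, **f0_kwargs)
    except ValueError:
        return (np.nan, np.nan, np.nan)
    voiced = np.nonzero(track.voiced)[0]
    if voiced.size == 0:
        return (np.nan, np.nan, np.nan)
    first = track.f0[voiced[0]]
    last = track.f0[voiced[-1]]
    # temporally central voiced analysis window
    centre_t = (track.times[0] + track.times[-1]) / 2
    mid = voiced[np.argmin(np.abs(track.times[voiced] - centre_t))]
    middle = track.f0[mid]
    return (float(np.mean(track.f0[voiced])),
            float(first - middle), float(middle - last))


def measure_segment(waveform: np.ndarray, span: tuple[float, float],
                    params: SpectrogramParams, **f0_kwargs) -> SegmentFeatures:
    """Measure the 14 parameters on ``waveform[span]``.

    Energy quartiles and the -20 dB band edges come from the mean power
    spectrum over frames in the span; the ``*_max`` quartile variants
    from the single frame with maximum in-band power; F0-derived values
    from :func:`estimate_f0` (NaN when the segment is unvoiced).
    """
    start_s, end_s = span
    sr = params.sample_rate
    n = np.asarray(waveform).size
    i0, i1 = int(round(start_s * sr)), int(round(end_s * sr))
    if not (0 <= i0 < i1 <= n):
        raise ValueError(f"span ({start_s:.6f}, {end_s:.6f}) s outside audio of "
                         f"{n / sr:.6f} s")
    seg = np.asarray(waveform, dtype=float)[i0:i1]
    if not np.any(seg):
        raise ValueError("segment is all zero")

    spec = compute_spectrogram(seg, params)
    mean_spectrum = spec.power.mean(axis=0)
    q25m, q50m, q75m = _quartile_freqs(mean_spectrum, spec.freqs)
    min_freq, max_freq = _band_edges(mean_spectrum, spec.freqs)
    peak_freq = float(spec.freqs[int(np.argmax(mean_spectrum))])

    max_frame = spec.power[int(np.argmax(spec.power.sum(axis=1)))]
    q25x, q50x, q75x = _quartile_freqs(max_frame, spec.freqs)

    f0_mean, onset, offset = _f0_features(seg, sr, **f0_kwargs)

    return SegmentFeatures(
        duration=float(end_s - start_s),
        bandwidth_mean=max_freq - min_freq,
        f0_mean=f0_mean, onset=onset, offset=offset,
        max_freq=max_freq, min_freq=min_freq,
        peak_frequency_mean=peak_freq,
        q25_mean=q25m, q50_mean=q50m, q75_mean=q75m,
        q25_max=q25x, q50_max=q50x, q75_max=q75x)


def _spans(row: pd.Series) -> dict[str, tuple[float, float] | None]:
    harmonic = None
    if pd.notna(row.get("harmonic_start")) and pd.notna(row.get("harmonic_end")):
        harmonic = (float(row["harmonic_start"]), float(row["harmonic_end"]))
    return {
        "whole": (float(row["whole_start"]), float(row["whole_end"])),
        "noisy": (float(row["noisy_start"]), float(row["noisy_end"])),
        "harmonic": harmonic,
    }


def extract_features(annotations: pd.DataFrame, audio_root: Path | str,
                     params: SpectrogramParams | None = None,
                     **f0_kwargs) -> pd.DataFrame:
    """Measure every call's whole/noisy/harmonic segments.

    Returns one row per (call, present segment kind) with the call's
    factors and the 14 features. Harmonic rows are absent where the
    annotation lacks a harmonic span; unreadable spans are excluded
    with a log entry. A per-individual-per-context call count is
    attached as ``result.attrs["completeness"]``.
    """
    from .synth import read_wav

    audio_root = Path(audio_root)
    missing = [row.call_id for row in annotations.itertuples()
               if not (audio_root / row.audio_path).exists()]
    if missing:
        raise FileNotFoundError(
            f"audio missing for call_id(s): {', '.join(map(str, missing))}")

    rows = []
    for _, ann in annotations.iterrows():
        wave, sr = read_wav(audio_root / ann["audio_path"])
        p = params or SpectrogramParams(sample_rate=sr)
        if p.sample_rate != sr:
            raise ValueError(f"call {ann['call_id']}: sample rate {sr} does not "
                             f"match analysis params {p.sample_rate}")
        for kind, span in _spans(ann).items():
            if span is None:
                continue
            try:
                feats = measure_segment(wave, span, p, **f0_kwargs)
            except ValueError as exc:
                log.warning("call %s %s segment excluded: %s",
                            ann["call_id"], kind, exc)
                continue
            row = {"call_id": ann["call_id"], "segment": kind}
            for col in FACTOR_COLUMNS:
                row[col] = ann[col]
            row.update(feats.as_dict())
            rows.append(row)

    table = pd.DataFrame(rows, columns=["call_id", "segment", *FACTOR_COLUMNS,
                                        *FEATURE_COLUMNS])
    whole = table[table["segment"] == "whole"]
    completeness = (whole.groupby(["individual_id", "context"])["call_id"]
                    .count().unstack(fill_value=0))
    table.attrs["completeness"] = completeness
    return table


def write_features(table: pd.DataFrame, path: Path | str) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_features(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"call_id": str, "individual_id": str,
                                    "group_id": str})
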