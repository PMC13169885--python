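"""Acoustic feature extraction: pause detection and amplitude statistics.

The six acoustic variables are the pause ratios (cumulative pause per total
speaking duration, cumulative pause per word) and four amplitude measures
(peak, maximum peak, minimum peak, average peak).  Pause detection
re-specifies an audio editor's "delete silence" operation as an explicit
algorithm:

* the short-window RMS envelope is computed with 10 ms windows at a 5 ms
  hop;
* the reference level is the recording's maximum short-window RMS, and a
  frame is silent when its envelope lies at least ``threshold_db`` (default
  35 dB) below that reference — the threshold is relative, since consumer
  editors define silence relative to programme level;
* maximal runs of silent frames whose spanned duration reaches ``min_ms``
  (default 200 ms) become pauses; durations beyond ``max_ms`` (default
  500 ms) are credited at the cap (emulating silence deletion with a
  maximum deletion length).  Sub-200 ms quiet gaps are treated as
  articulatory, not cognitive, pauses.

Cumulative pause is the sum of credited durations, matching the
original-minus-shortened construction of the editor workflow.  The average
peak amplitude is RMS power multiplied by 1.414 (the sinusoidal
peak-to-RMS crest factor, sqrt(2) to three decimals).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
from scipy.io import wavfile
from scipy.signal import istft, stft

from .errors import InputError, UndefinedFeatureError

#: sinusoidal crest factor used by the average-peak rule
PEAK_TO_RMS = 1.414

DEFAULT_THRESHOLD_DB = 35.0
DEFAULT_MIN_MS = 200.0
DEFAULT_MAX_MS = 500.0
DEFAULT_WIN_MS = 10.0
DEFAULT_HOP_MS = 5.0


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be positive")
        if len(self.samples) == 0:
            raise InputError("waveform must be nonempty")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class PauseInterval:
    start_s: float
    end_s: float
    counted_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise InputError("pause interval must have end > start")
        if not 0 <= self.counted_s <= (self.end_s - self.start_s) + 1e-9:
            raise InputError("counted_s must lie in [0, duration]")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class AudioFeatureSet:
    total_duration_s: float
    pause_total_s: float
    pause_per_duration: float
    pause_per_word: float
    peak_amplitude: float
    max_peak_amplitude: float
    min_peak_amplitude: float
    average_peak_amplitude: float

    def as_dict(self) -> dict:
        return {
            "pause_per_duration": self.pause_per_duration,
            "pause_per_word": self.pause_per_word,
            "peak_amplitude": self.peak_amplitude,
            "max_peak_amplitude": self.max_peak_amplitude,
            "min_peak_amplitude": self.min_peak_amplitude,
            "average_peak_amplitude": self.average_peak_amplitude,
        }


AUDIO_FEATURES = ("pause_per_duration", "pause_per_word", "peak_amplitude",
                  "max_peak_amplitude", "min_peak_amplitude",
                  "average_peak_amplitude")


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM WAV file to full-scale floats; stereo is downmixed by
    channel averaging."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:  # covers 24-bit PCM promoted to int32
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:
        samples = data.astype(np.float64)
    return Waveform(samples, int(rate))


def _check_finite(samples: np.ndarray) -> None:
    if not np.all(np.isfinite(samples)):
        raise InputError("waveform contains non-finite samples")


def rms_envelope(w: Waveform, win_ms: float = DEFAULT_WIN_MS,
                 hop_ms: float = DEFAULT_HOP_MS
                 ) -> Tuple[np.ndarray, np.ndarray, int]:
    """Short-window RMS envelope; returns (frame start samples, rms, win)."""
    win = int(round(win_ms / 1000.0 * w.sample_rate))
    hop = int(round(hop_ms / 1000.0 * w.sample_rate))
    if win < 1 or hop < 1 or len(w.samples) < win:
        return np.zeros(0, dtype=int), np.zeros(0), max(win, 1)
    sq = np.square(w.samples.astype(np.float64))
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    starts = np.arange(0, len(w.samples) - win + 1, hop)
    rms = np.sqrt((csum[starts + win] - csum[starts]) / win)
    return starts, rms, win


def detect_pauses(w: Waveform,
                  threshold_db: float = DEFAULT_THRESHOLD_DB,
                  min_ms: float = DEFAULT_MIN_MS,
                  max_ms: float = DEFAULT_MAX_MS,
                  win_ms: float = DEFAULT_WIN_MS,
                  hop_ms: float = DEFAULT_HOP_MS,
                  cap_long: bool = True) -> List[PauseInterval]:
    """Find pauses: maximal sub-threshold envelope runs of >= ``min_ms``.

    ``counted_s`` credits at most ``max_ms`` per pause when ``cap_long``
    (default); with ``cap_long=False`` longer silences are excluded
    entirely.
    """
    if min_ms >= max_ms:
        raise InputError("min_ms must be < max_ms")
    if threshold_db <= 0:
        raise InputError("threshold_db must be positive")
    _check_finite(w.samples)
    starts, rms, win = rms_envelope(w, win_ms, hop_ms)
    if len(starts) == 0:
        return []
    ref = float(rms.max())
    if ref <= 0:
        return []
    silent = rms <= ref * 10.0 ** (-threshold_db / 20.0)
    sr = w.sample_rate
    min_samples = int(round(min_ms / 1000.0 * sr))
    max_s = max_ms / 1000.0

    pauses: List[PauseInterval] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], silent.view(np.int8),
                                                   [0]))))
    for lo, hi in zip(edges[::2], edges[1::2]):
        first, last = starts[lo], starts[hi - 1]
        span = (last - first) + win  # samples covered by the silent run
        if span < min_samples:
            continue
        dur_s = span / sr
        if not cap_long and dur_s > max_s:
            continue
        pauses.append(PauseInterval(
            start_s=first / sr, end_s=(last + win) / sr,
            counted_s=min(dur_s, max_s)))
    return pauses


def cumulative_pause(pauses: Sequence[PauseInterval]) -> float:
    """Total credited pause time (original minus silence-deleted length)."""
    return float(sum(p.counted_s for p in pauses))


def pause_ratios(pause_total_s: float, total_duration_s: float,
                 word_count: int) -> Tuple[float, float]:
    """(pause per total speaking duration, pause per word)."""
    if total_duration_s <= 0:
        raise UndefinedFeatureError("total_duration_s must be positive")
    if word_count <= 0:
        raise UndefinedFeatureError("word_count must be positive")
    return pause_total_s / total_duration_s, pause_total_s / word_count


def amplitude_stats(w: Waveform) -> Tuple[float, float, float, float]:
    """(peak, max_peak, min_peak, average_peak); average = RMS x 1.414."""
    _check_finite(w.samples)
    s = w.samples.astype(np.float64)
    rms = float(np.sqrt(np.mean(np.square(s))))
    return (float(np.max(np.abs(s))), float(np.max(s)), float(np.min(s)),
            rms * PEAK_TO_RMS)


def reduce_noise(w: Waveform, profile_s: float = 0.0,
                 gate_factor: float = 2.0,
                 attenuation: float = 0.02) -> Waveform:
    """Spectral gate using the recording's quietest frames as noise profile.

    The ``profile_s`` lowest-energy seconds of STFT frames estimate the
    per-bin noise magnitude; bins below ``gate_factor`` times that profile
    are attenuated.  ``profile_s = 0`` is the identity (the stage defaults
    to off for clean synthetic input).  Output length equals input length.
    """
    if profile_s < 0:
        raise InputError("profile_s must be >= 0")
    if profile_s == 0:
        return w
    _check_finite(w.samples)
    nperseg = 256
    if len(w.samples) < nperseg:
        return w
    f, t, Z = stft(w.samples, fs=w.sample_rate, nperseg=nperseg)
    mag = np.abs(Z)
    frame_energy = mag.sum(axis=0)
    frame_dt = t[1] - t[0] if len(t) > 1 else w.duration_s
    n_profile = max(1, min(len(t), int(round(profile_s / frame_dt))))
    quiet = np.argsort(frame_energy)[:n_profile]
    noise_profile = mag[:, quiet].mean(axis=1, keepdims=True)
    gain = np.where(mag > gate_factor * noise_profile, 1.0, attenuation)
    _, out = istft(Z * gain, fs=w.sample_rate, nperseg=nperseg)
    if len(out) < len(w.samples):
        out = np.pad(out, (0, len(w.samples) - len(out)))
    return Waveform(out[:len(w.samples)], w.sample_rate)


def extract_audio_features(w: Waveform, word_count: int,
                           threshold_db: float = DEFAULT_THRESHOLD_DB,
                           min_ms: float = DEFAULT_MIN_MS,
                           max_ms: float = DEFAULT_MAX_MS,
                           noise_profile_s: float = 0.0) -> AudioFeatureSet:
    """Full acoustic feature block for one subject.

    Amplitude statistics are computed on the (optionally noise-reduced)
    pause-intact signal; the pause ratios use the original recording
    duration as total speaking time.
    """
    wproc = reduce_noise(w, noise_profile_s)
    pauses = detect_pauses(wproc, threshold_db, min_ms, max_ms)
    pause_total = cumulative_pause(pauses)
    per_dur, per_word = pause_ratios(pause_total, w.duration_s, word_count)
    peak, max_peak, min_peak, avg_peak = amplitude_stats(wproc)
    return AudioFeatureSet(
        total_duration_s=w.duration_s,
        pause_total_s=pause_total,
        pause_per_duration=per_dur,
        pause_per_word=per_word,
        peak_amplitude=peak,
        max_peak_amplitude=max_peak,
        min_peak_amplitude=min_peak,
        average_peak_amplitude=avg_peak,
    )
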