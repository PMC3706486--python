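"""Acoustic front-end: speech-activity detection and MFCC+energy features.

The feature layout is fixed at 60 columns per 10 ms frame: 19 mel cepstra
plus log energy (20 static), followed by their first and second time
derivatives.  Framing uses a 25 ms Hamming window with a 10 ms advance; the
mel scale, triangular filterbank and cepstral DCT follow the HTK convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.io.wavfile
import scipy.signal

WINDOW_S = 0.025
ADVANCE_S = 0.010
N_CEPSTRA = 19
N_STATIC = N_CEPSTRA + 1  # + log energy
N_FEATURES = 3 * N_STATIC  # static | delta | delta-delta
LOG_FLOOR = 1e-10


class EmptySpeechError(ValueError):
    """No speech-active frames were found in the recording."""


@dataclass(frozen=True)
class Recording:
    """A mono utterance: samples (float), sample rate, and an identifier."""

    samples: np.ndarray
    sample_rate: int
    recording_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError("recording must be mono (1-D samples)")
        object.__setattr__(self, "samples", arr)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    @classmethod
    def from_wav(cls, path, recording_id: str = "") -> "Recording":
        """Read a 16-bit mono PCM WAV file, scaling samples to [-1, 1]."""
        rate, data = scipy.io.wavfile.read(path)
        if data.ndim != 1:
            raise ValueError(f"{path}: expected mono WAV")
        if data.dtype == np.int16:
            samples = data.astype(float) / 32768.0
        else:
            samples = data.astype(float)
        return cls(samples, int(rate), recording_id or str(path))

    def to_wav(self, path) -> None:
        clipped = np.clip(self.samples, -1.0, 1.0)
        scipy.io.wavfile.write(path, self.sample_rate, (clipped * 32767).astype(np.int16))


@dataclass(frozen=True)
class FeatureMatrix:
    """T x 60 feature frames with the fixed [static | Δ | ΔΔ] layout."""

    frames: np.ndarray
    frame_advance_s: float = ADVANCE_S
    window_s: float = WINDOW_S

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must be T x {N_FEATURES}")
        if arr.shape[0] < 1:
            raise ValueError("feature matrix must have at least one frame")
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature matrix contains non-finite values")
        object.__setattr__(self, "frames", arr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @staticmethod
    def column_names() -> list[str]:
        names = [f"c{i}" for i in range(1, N_CEPSTRA + 1)] + ["log_energy"]
        return names + [f"d_{n}" for n in names] + [f"dd_{n}" for n in names]


def hz_to_mel(f):
    """HTK mel scale: Mel(f) = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _frame_signal(x: np.ndarray, sample_rate: int) -> np.ndarray:
    win = int(round(WINDOW_S * sample_rate))
    hop = int(round(ADVANCE_S * sample_rate))
    if len(x) < win:
        raise ValueError(
            f"recording shorter than one analysis window ({len(x)} < {win} samples)"
        )
    n_frames = 1 + (len(x) - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _frame_energies_db(x: np.ndarray, sample_rate: int) -> np.ndarray:
    frames = _frame_signal(x, sample_rate)
    e = np.sum(frames**2, axis=1)
    peak = e.max()
    if peak <= 0:
        return np.full(len(e), -np.inf)
    return 10.0 * np.log10(np.maximum(e, LOG_FLOOR * peak) / peak)


def detect_speech(
    rec: Recording,
    energy_threshold_db: float = 30.0,
    min_speech_s: float = 0.1,
    hangover_s: float = 0.1,
) -> Recording:
    """Energy-threshold speech-activity detection.

    Frames within ``energy_threshold_db`` of the peak frame energy are
    speech; a hangover extends each speech region so that brief intra-word
    dips are kept.  Returns the concatenation of speech-active samples.
    Utterances with at least ``min_speech_s`` of speech always survive;
    an all-silent recording raises :class:`EmptySpeechError`.
    """
    x = rec.samples
    if len(x) == 0 or np.max(np.abs(x)) == 0:
        raise EmptySpeechError(f"{rec.recording_id or 'recording'}: no speech detected")
    db = _frame_energies_db(x, rec.sample_rate)
    active = db > -energy_threshold_db
    if not active.any():
        raise EmptySpeechError(f"{rec.recording_id or 'recording'}: no speech detected")

    hang = max(0, int(round(hangover_s / ADVANCE_S)))
    if hang:
        kernel = np.ones(hang + 1)
        active = np.convolve(active.astype(float), kernel, mode="full")[: len(active)] > 0

    hop = int(round(ADVANCE_S * rec.sample_rate))
    win = int(round(WINDOW_S * rec.sample_rate))
    keep = np.zeros(len(x), dtype=bool)
    starts = np.flatnonzero(active) * hop
    for s in starts:
        keep[s : s + win] = True
    out = x[keep]
    if len(out) < min_speech_s * rec.sample_rate:
        # guarantee short valid utterances are never discarded
        out = x
    return Recording(out, rec.sample_rate, rec.recording_id)


def mel_filterbank(sample_rate: int, n_channels: int = 26, n_fft: int = 512) -> np.ndarray:
    """Triangular mel filterbank, (n_channels x n_fft//2+1), peak weight 1.

    Filter centers are equally spaced on the mel scale between 0 Hz and the
    Nyquist frequency.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 filterbank channels")
    n_bins = n_fft // 2 + 1
    if n_bins < n_channels + 2:
        raise ValueError("n_fft too small for the requested channel count")
    mel_edges = np.linspace(0.0, hz_to_mel(sample_rate / 2.0), n_channels + 2)
    bin_mels = hz_to_mel(np.arange(n_bins) * sample_rate / n_fft)
    fb = np.zeros((n_channels, n_bins))
    for ch in range(n_channels):
        lo, center, hi = mel_edges[ch], mel_edges[ch + 1], mel_edges[ch + 2]
        up = (bin_mels - lo) / (center - lo)
        down = (hi - bin_mels) / (hi - center)
        fb[ch] = np.clip(np.minimum(up, down), 0.0, None)
    # renormalize each triangle so its sampled maximum is exactly 1
    fb /= fb.max(axis=1, keepdims=True)
    return fb


def dct_cepstra(log_fb: np.ndarray, n_cepstra: int = N_CEPSTRA) -> np.ndarray:
    """HTK-style DCT of log filterbank amplitudes, cepstra 1..n_cepstra.

    c_i = sqrt(2/N) * sum_j m_j cos(pi * i * (j - 0.5) / N); the 0th
    coefficient (overall level) is deliberately excluded — level information
    is carried by the log-energy column instead.
    """
    n_ch = log_fb.shape[-1]
    j = np.arange(1, n_ch + 1)
    i = np.arange(1, n_cepstra + 1)
    basis = np.sqrt(2.0 / n_ch) * np.cos(np.pi * np.outer(i, (j - 0.5)) / n_ch)
    return log_fb @ basis.T


def deltas(x: np.ndarray, window: int = 2) -> np.ndarray:
    """Regression-slope time derivatives with edge replication.

    d_t = sum_{k=1..w} k (x_{t+k} - x_{t-k}) / (2 sum k^2).
    """
    T = x.shape[0]
    denom = 2.0 * sum(k * k for k in range(1, window + 1))
    padded = np.concatenate([np.repeat(x[:1], window, axis=0), x, np.repeat(x[-1:], window, axis=0)])
    out = np.zeros_like(x)
    for k in range(1, window + 1):
        out += k * (padded[window + k : window + k + T] - padded[window - k : window - k + T])
    return out / denom


def extract_features(
    rec: Recording,
    n_channels: int = 26,
    n_fft: int | None = None,
    delta_window: int = 2,
) -> FeatureMatrix:
    """Full front-end: frame, window, filterbank, DCT, energy, Δ and ΔΔ."""
    sr = rec.sample_rate
    frames = _frame_signal(rec.samples, sr)
    win = frames.shape[1]
    if n_fft is None:
        n_fft = int(2 ** np.ceil(np.log2(win)))
    hamming = scipy.signal.get_window("hamming", win, fftbins=False)
    windowed = frames * hamming

    spectrum = np.abs(np.fft.rfft(windowed, n=n_fft)) ** 2
    fb = mel_filterbank(sr, n_channels, n_fft)
    fb_energies = spectrum @ fb.T
    log_fb = np.log(np.maximum(fb_energies, LOG_FLOOR))
    cepstra = dct_cepstra(log_fb)

    energy = np.log(np.maximum(np.sum(frames**2, axis=1), LOG_FLOOR))
    static = np.column_stack([cepstra, energy])
    d1 = deltas(static, delta_window)
    d2 = deltas(d1, delta_window)
    return FeatureMatrix(np.column_stack([static, d1, d2]))
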