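"""Audio front-end: WAV reading, resampling, slicing, spectrograms.

The classifier consumes fixed-geometry spectrogram images. Audio is
brought to a common 96 kHz rate (manatee vocal energy stays below
~43 kHz, so higher field rates carry no extra information), cut into
0.2 s windows of exactly 19,200 samples, and transformed into a
peak-normalized dB magnitude spectrogram of 513 frequency bins by 75
time frames (93.75 Hz by ~2.67 ms resolution).

Framing convention
------------------
75 frames equals ``floor(19200 / 256)``, which neither a centered STFT
(76 frames) nor an uncentered no-pad STFT (72) produces. Frames are
therefore taken at offsets ``k * hop`` for ``k = 0..74`` with the signal
zero-padded at the tail so the last 1024-sample frame is complete. The
printed geometry is treated as an interoperability contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "TARGET_RATE_HZ",
    "WINDOW_S",
    "N_FFT",
    "HOP",
    "SLICE_SAMPLES",
    "N_FREQ",
    "N_TIME",
    "AudioSegment",
    "Spectrogram",
    "read_wav",
    "write_wav",
    "resample",
    "slice_audio",
    "spectrogram",
]

TARGET_RATE_HZ = 96_000
WINDOW_S = 0.2
N_FFT = 1024
HOP = 256
SLICE_SAMPLES = int(round(TARGET_RATE_HZ * WINDOW_S))  # 19,200
N_FREQ = N_FFT // 2 + 1  # 513
N_TIME = SLICE_SAMPLES // HOP  # 75

_AMIN = 1e-10


@dataclass(frozen=True)
class AudioSegment:
    """A mono waveform slice with its sample rate and provenance."""

    samples: np.ndarray
    rate_hz: int
    origin: tuple[str, float] = ("", 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D mono waveform")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class Spectrogram:
    """Peak-normalized dB magnitude spectrogram, frequency x time in [0,1]."""

    values: np.ndarray
    freq_resolution_hz: float = TARGET_RATE_HZ / N_FFT  # 93.75
    time_resolution_s: float = HOP / TARGET_RATE_HZ  # ~2.67 ms

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (freq x time)")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("spectrogram values must lie in [0, 1]")

    @property
    def n_freq(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file as float64 in [-1, 1]; mono enforced.

    16/32-bit PCM and float encodings are supported. Multi-channel files
    are reduced to the first channel with a warning.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        warnings.warn(
            f"{Path(path).name}: {data.shape[1]} channels; taking channel 0",
            stacklevel=2,
        )
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    return samples, int(rate)


def write_wav(path: str | Path, samples: np.ndarray, rate_hz: int) -> Path:
    """Write a waveform as 16-bit PCM WAV, clipping to [-1, 1]."""
    path = Path(path)
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    wavfile.write(str(path), rate_hz, np.round(x * 32767.0).astype(np.int16))
    return path


def resample(
    samples: np.ndarray,
    rate_hz: int,
    target_hz: int = TARGET_RATE_HZ,
    *,
    origin: tuple[str, float] = ("", 0.0),
) -> AudioSegment:
    """Anti-aliased polyphase resampling down to ``target_hz``.

    Upsampling is rejected: field recorders sample at or above 96 kHz
    and upsampling would fabricate bandwidth. Output length is
    ``round(len(samples) * target_hz / rate_hz)``; a 96 kHz input is
    returned unchanged bit-exactly.
    """
    if rate_hz <= 0 or target_hz <= 0:
        raise ValueError("sample rates must be positive")
    if rate_hz < target_hz:
        raise ValueError(
            f"upsampling {rate_hz} -> {target_hz} Hz rejected; record at "
            ">= 96 kHz or resample externally"
        )
    x = np.asarray(samples, dtype=np.float64)
    if rate_hz == target_hz:
        return AudioSegment(x, target_hz, origin)
    frac = Fraction(target_hz, rate_hz)
    up, down = frac.numerator, frac.denominator
    # a long Kaiser FIR keeps the passband out to ~0.94 Nyquist while
    # attenuating everything above the output Nyquist by > 40 dB
    max_rate = max(up, down)
    n_half = 32 * max_rate
    h = sps.firwin(2 * n_half + 1, 0.94 / max_rate, window=("kaiser", 7.0))
    y = sps.resample_poly(x, up, down, window=h * up)
    n_out = int(round(len(x) * target_hz / rate_hz))
    if len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)))
    return AudioSegment(y[:n_out], target_hz, origin)


def slice_audio(
    samples: np.ndarray,
    window_s: float = WINDOW_S,
    stride_s: float = WINDOW_S,
    *,
    rate_hz: int = TARGET_RATE_HZ,
    recording_id: str = "",
) -> list[AudioSegment]:
    """Cut a 96 kHz waveform into fixed windows (trailing partial dropped).

    Slice ``k`` starts at sample ``round(k * stride_s * rate_hz)`` and has
    exactly ``round(window_s * rate_hz)`` samples.
    """
    if rate_hz != TARGET_RATE_HZ:
        raise ValueError(f"slice_audio expects {TARGET_RATE_HZ} Hz audio")
    x = np.asarray(samples, dtype=np.float64)
    win = int(round(window_s * rate_hz))
    stride = int(round(stride_s * rate_hz))
    if win <= 0 or stride <= 0:
        raise ValueError("window_s and stride_s must be positive")
    out = []
    k = 0
    while k * stride + win <= len(x):
        start = k * stride
        out.append(
            AudioSegment(
                x[start : start + win],
                rate_hz,
                origin=(recording_id, start / rate_hz),
            )
        )
        k += 1
    return out


def _frame(x: np.ndarray, n_frames: int) -> np.ndarray:
    """Frames at offsets k*HOP, k = 0..n_frames-1, tail zero-padded."""
    need = (n_frames - 1) * HOP + N_FFT
    if len(x) < need:
        x = np.pad(x, (0, need - len(x)))
    view = np.lib.stride_tricks.sliding_window_view(x, N_FFT)[::HOP]
    return view[:n_frames]


def spectrogram(segment: AudioSegment, n_fft: int = N_FFT, hop: int = HOP) -> Spectrogram:
    """Peak-normalized dB magnitude spectrogram of a standard slice.

    Magnitude STFT (periodic Hann window) with frames at offsets
    ``k * hop``; one-sided bins 0..n_fft/2; amplitude dB via
    ``20 * log10(max(|S|, 1e-10))``; then min-max normalized to [0, 1].
    A constant input (all dB values equal) maps to all zeros.

    Inputs shorter than 19,200 samples are zero-padded; a standard
    0.2 s / 96 kHz slice yields exactly 513 x 75.
    """
    if segment.rate_hz != TARGET_RATE_HZ:
        raise ValueError(f"spectrogram expects {TARGET_RATE_HZ} Hz audio")
    if n_fft != N_FFT or hop != HOP:
        raise ValueError("non-default STFT geometry is not supported")
    x = segment.samples
    if len(x) > SLICE_SAMPLES:
        raise ValueError(
            f"slice has {len(x)} samples; expected <= {SLICE_SAMPLES}"
        )
    if len(x) < SLICE_SAMPLES:
        x = np.pad(x, (0, SLICE_SAMPLES - len(x)))
    frames = _frame(x, N_TIME)  # (75, 1024)
    window = sps.get_window("hann", N_FFT, fftbins=True)
    mag = np.abs(np.fft.rfft(frames * window, axis=1)).T  # (513, 75)
    db = 20.0 * np.log10(np.maximum(mag, _AMIN))
    lo, hi = db.min(), db.max()
    if hi - lo < 1e-12:
        return Spectrogram(np.zeros_like(db))
    return Spectrogram((db - lo) / (hi - lo))
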