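"""Stochastic waveform augmentation (training-time only).

Each training slice passes through a gate that fires with probability
0.9; when it fires, three transforms are considered independently, in a
fixed order, each with its own probability:

1. time stretch (p = 0.5, rate uniform in [0.9, 1.1]), length restored
   to 19,200 samples by tail zero-pad (rate < 1) or symmetric trim;
2. time mask (p = 0.5): a contiguous 5-20 % run of samples zeroed at a
   uniform position;
3. band-stop (p = 0.5): zero-phase Butterworth band-reject around a
   center uniform in [0, 43 kHz] with bandwidth 5-20 % of that center.

Validation and test audio is never augmented. All randomness flows
through an explicit generator, so identical (input, config, seed) give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from sirenet.features import SLICE_SAMPLES, TARGET_RATE_HZ, AudioSegment

__all__ = ["AugmentConfig", "augment_waveform", "augmentation_rate"]


@dataclass(frozen=True)
class AugmentConfig:
    """Probabilities and sampling ranges of the augmentation pipeline."""

    gate_p: float = 0.9
    stretch_p: float = 0.5
    stretch_rate: tuple[float, float] = (0.9, 1.1)
    timemask_p: float = 0.5
    timemask_fraction: tuple[float, float] = (0.05, 0.20)
    bandstop_p: float = 0.5
    bandstop_center_hz: tuple[float, float] = (0.0, 43_000.0)
    bandstop_bandwidth_fraction: tuple[float, float] = (0.05, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gate_p", "stretch_p", "timemask_p", "bandstop_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in (
            "stretch_rate",
            "timemask_fraction",
            "bandstop_center_hz",
            "bandstop_bandwidth_fraction",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must be ordered, got ({lo}, {hi})")


def _uniform(rng: np.random.Generator, lohi: tuple[float, float]) -> float:
    lo, hi = lohi
    return lo if lo == hi else float(rng.uniform(lo, hi))


def _time_stretch(x: np.ndarray, rate: float) -> np.ndarray:
    """Stretch the slice in time by ``rate`` then restore its length.

    ``rate`` is a duration factor: rate > 1 lengthens the slice and the
    excess is trimmed symmetrically (the window stays centered on the
    same content); rate < 1 shortens it and the tail is zero-padded.
    """
    n = len(x)
    frac = Fraction(rate).limit_denominator(100)
    y = sps.resample_poly(x, frac.numerator, frac.denominator)
    if len(y) >= n:
        start = (len(y) - n) // 2
        return y[start : start + n]
    return np.pad(y, (0, n - len(y)))


def _band_stop(
    x: np.ndarray, center_hz: float, bw_fraction: float, rate_hz: int
) -> np.ndarray:
    """Zero-phase order-4 Butterworth band-reject around ``center_hz``."""
    nyq = rate_hz / 2.0
    half_bw = center_hz * bw_fraction / 2.0
    lo = max(center_hz - half_bw, 1.0)
    hi = min(center_hz + half_bw, 0.999 * nyq)
    if hi <= lo:
        return x
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandstop", output="sos")
    return sps.sosfiltfilt(sos, x)


def augment_waveform(
    segment: AudioSegment,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> AudioSegment:
    """Apply the seeded augmentation pipeline to one training slice.

    With probability ``1 - gate_p`` the input is returned unchanged.
    The output always has the input's sample count.
    """
    if segment.rate_hz != TARGET_RATE_HZ:
        raise ValueError(f"augmentation expects {TARGET_RATE_HZ} Hz audio")
    x = segment.samples
    n = len(x)
    if rng.random() >= config.gate_p:
        return segment
    if rng.random() < config.stretch_p:
        x = _time_stretch(x, _uniform(rng, config.stretch_rate))
    if rng.random() < config.timemask_p:
        frac = _uniform(rng, config.timemask_fraction)
        m = int(round(frac * n))
        if m > 0:
            start = int(rng.integers(0, n - m + 1))
            x = x.copy()
            x[start : start + m] = 0.0
    if rng.random() < config.bandstop_p:
        center = _uniform(rng, config.bandstop_center_hz)
        bw = _uniform(rng, config.bandstop_bandwidth_fraction)
        x = _band_stop(x, center, bw, segment.rate_hz)
    assert len(x) == n
    return AudioSegment(x, segment.rate_hz, segment.origin)


def augmentation_rate(
    n_draws: int, config: AugmentConfig, rng: np.random.Generator
) -> float:
    """Empirical gate-firing fraction over ``n_draws`` (expectation gate_p).

    A statistical self-test: draws only the gate variable, consuming the
    same stream the pipeline would.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for a stable estimate")
    fired = sum(rng.random() < config.gate_p for _ in range(n_draws))
    return fired / n_draws
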