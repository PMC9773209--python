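"""Sampled-waveform container and level utilities.

All DSP in the package operates on :class:`AudioSignal`, a thin immutable
wrapper around a 1-D float array plus its sample rate. Amplitudes are
dimensionless with a nominal working range of [-1, 1]; levels are therefore
always *relative* (dB re another signal), never absolute SPL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioSignal",
    "rms",
    "rms_normalize",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class AudioSignal:
    """A sampled waveform.

    Parameters
    ----------
    samples : array-like of float
        Amplitude values. Stored as a read-only 1-D float64 array.
    sample_rate : float
        Sampling rate in Hz; must be positive.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if arr.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must all be finite")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "sample_rate", float(self.sample_rate))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def replace_samples(self, samples: np.ndarray) -> "AudioSignal":
        return AudioSignal(samples, self.sample_rate)


def rms(signal: AudioSignal | np.ndarray, mask: np.ndarray | None = None) -> float:
    """Root-mean-square amplitude, optionally restricted to a boolean mask."""
    x = signal.samples if isinstance(signal, AudioSignal) else np.asarray(signal, float)
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != x.shape:
            raise ValueError("mask length must match signal length")
        x = x[mask]
        if x.size == 0:
            raise ValueError("mask selects no samples")
    return float(np.sqrt(np.mean(np.square(x))))


def rms_normalize(
    signal: AudioSignal,
    target_rms: float,
    scope: str = "whole",
    segment_map=None,
) -> AudioSignal:
    """Scale a signal so its RMS over ``scope`` equals ``target_rms``.

    ``scope`` is ``"whole"`` (every sample) or ``"active_segments"`` (only
    samples inside the speech-labelled intervals of ``segment_map``). The
    operation is a pure scaling: waveform shape is preserved exactly.

    Raises
    ------
    ValueError
        If the signal is all-zero over the chosen scope (nothing to scale),
        or ``scope="active_segments"`` without a segment map.
    """
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    if scope == "whole":
        mask = None
    elif scope == "active_segments":
        if segment_map is None:
            raise ValueError("scope='active_segments' requires a segment map")
        mask = segment_map.mask("speech")
    else:
        raise ValueError(f"unknown scope {scope!r}")
    current = rms(signal, mask)
    if current == 0.0:
        raise ValueError("cannot normalize an all-zero signal")
    return signal.replace_samples(signal.samples * (target_rms / current))


def read_wav(path) -> AudioSignal:
    """Read a mono WAV file (PCM16/PCM32 or float32/float64).

    Integer encodings are rescaled to [-1, 1]. Multi-channel files are
    rejected: the paradigm is diotic, stimuli are stored mono.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:  # unsupported encoding
        raise IOError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 1:
        raise IOError(f"{path} is not mono ({data.ndim} channels)")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise IOError(f"unsupported WAV sample format {data.dtype}")
    return AudioSignal(samples, float(rate))


def write_wav(signal: AudioSignal, path, subtype: str = "float32") -> None:
    """Write a signal as WAV; ``subtype`` is ``"float32"`` or ``"pcm16"``."""
    path = Path(path)
    if subtype == "float32":
        data = signal.samples.astype(np.float32)
    elif subtype == "pcm16":
        scaled = np.round(np.clip(signal.samples, -1.0, 1.0) * 32768.0)
        data = np.clip(scaled, -32768, 32767).astype(np.int16)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
    wavfile.write(path, int(round(signal.sample_rate)), data)
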