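"""Speech-shaped noise: corpus magnitude spectrum + phase randomization.

The noise that fills the gaps is shaped like the speech it replaces: its
long-term magnitude spectrum is taken from the pooled sentence corpus, and
waveforms are synthesized by drawing random phases for every spectral
component and inverse-transforming. Because the spectrum is specified on the
one-sided (rfft) grid, the inverse transform is Hermitian by construction and
the output is exactly real.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioSignal

__all__ = ["NoiseModel", "build_noise_model", "synthesize_noise"]


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


@dataclass(frozen=True)
class NoiseModel:
    """One-sided magnitude spectrum of the pooled corpus.

    ``magnitude_spectrum`` holds nonnegative linear magnitudes on the rfft
    grid of ``fft_length`` points at ``sample_rate`` Hz.
    """

    magnitude_spectrum: np.ndarray
    fft_length: int
    sample_rate: float

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude_spectrum, dtype=np.float64)
        if mag.ndim != 1 or np.any(mag < 0) or not np.all(np.isfinite(mag)):
            raise ValueError("magnitude spectrum must be 1-D, finite, nonnegative")
        if mag.size != self.fft_length // 2 + 1:
            raise ValueError("bin count inconsistent with fft_length")
        mag = mag.copy()
        mag.flags.writeable = False
        object.__setattr__(self, "magnitude_spectrum", mag)

    @property
    def frequencies(self) -> np.ndarray:
        return np.fft.rfftfreq(self.fft_length, 1.0 / self.sample_rate)


def build_noise_model(corpus, fft_policy: str = "concat") -> NoiseModel:
    """Pool a sentence corpus into a magnitude-spectrum noise model.

    ``fft_policy="concat"`` (default) takes one FFT of the concatenated
    corpus, zero-padded to the next power of two — the most literal reading
    of a single combined transform of all sentences. ``"average"`` instead
    averages per-sentence magnitude spectra on a common grid.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus must be nonempty")
    rates = {s.sample_rate for s in corpus}
    if len(rates) != 1:
        raise ValueError(f"corpus has mixed sample rates: {sorted(rates)}")
    rate = rates.pop()
    if fft_policy == "concat":
        x = np.concatenate([s.samples for s in corpus])
        nfft = _next_pow2(x.size)
        mag = np.abs(np.fft.rfft(x, nfft))
    elif fft_policy == "average":
        nfft = _next_pow2(max(len(s) for s in corpus))
        mag = np.mean([np.abs(np.fft.rfft(s.samples, nfft)) for s in corpus], axis=0)
    else:
        raise ValueError(f"unknown fft_policy {fft_policy!r}")
    return NoiseModel(mag, nfft, rate)


def synthesize_noise(model: NoiseModel, n_samples: int, seed: int) -> AudioSignal:
    """Draw one noise realization with the model's spectral shape.

    The model magnitudes are interpolated onto the rfft grid of the requested
    length, every component gets an independent uniform random phase (DC and
    Nyquist stay real), and the result is inverse-transformed. Deterministic
    for a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    target_freqs = np.fft.rfftfreq(n_samples, 1.0 / model.sample_rate)
    mag = np.interp(target_freqs, model.frequencies, model.magnitude_spectrum)
    mag[0] = 0.0  # drop the corpus DC offset: noise is zero-mean
    phases = rng.uniform(0.0, 2.0 * np.pi, mag.size)
    phases[0] = 0.0
    if n_samples % 2 == 0:
        phases[-1] = 0.0
    spectrum = mag * np.exp(1j * phases)
    samples = np.fft.irfft(spectrum, n_samples)
    return AudioSignal(samples, model.sample_rate)
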