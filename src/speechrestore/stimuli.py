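"""Assembly of matched silent-gap / noise-burst stimulus pairs.

A sentence is gated into alternating speech and silence (the silent-gap
stimulus); speech-shaped noise is gated to the complementary intervals with
its own ramps, levelled against the speech, and added linearly to produce
the noise-burst stimulus. Both members share one segment map, so
``noise_burst - silent_gap`` recovers the gated noise sample-exactly.

Levels are set on the *active* intervals of each component (speech intervals
for the speech, gap intervals for the noise): with ``snr_db = -10`` the
noise bursts sit 10 dB above the speech segments, the configuration known to
maximize perceptual restoration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioSignal, rms, rms_normalize
from .gating import GatingSpec, SegmentMap, gate_signal, make_segment_map
from .noise import NoiseModel, synthesize_noise

__all__ = ["StimulusPair", "assemble_pair", "measure_snr_db"]


@dataclass(frozen=True)
class StimulusPair:
    """Matched silent-gap and noise-burst stimuli sharing one segment map."""

    silent_gap: AudioSignal
    noise_burst: AudioSignal
    segment_map: SegmentMap
    snr_db: float = -10.0

    def __post_init__(self) -> None:
        if len(self.silent_gap) != len(self.noise_burst):
            raise ValueError("pair members must have equal length")
        if self.silent_gap.sample_rate != self.noise_burst.sample_rate:
            raise ValueError("pair members must share a sample rate")
        if self.segment_map.n_samples != len(self.silent_gap):
            raise ValueError("segment map must cover the stimuli")

    @property
    def gated_noise(self) -> AudioSignal:
        """The noise component alone (noise_burst minus silent_gap)."""
        return self.noise_burst.replace_samples(
            self.noise_burst.samples - self.silent_gap.samples
        )


def assemble_pair(
    sentence: AudioSignal,
    spec: GatingSpec,
    model: NoiseModel,
    snr_db: float = -10.0,
    seed: int = 0,
    rms_target: float = 0.05,
    rms_scope: str = "active_segments",
) -> StimulusPair:
    """Build the silent-gap and noise-burst stimuli for one sentence.

    Steps: gate the sentence (with ramps) and normalize its RMS to
    ``rms_target``; synthesize full-length speech-shaped noise, gate it to
    the gap intervals (with the same ramp length), and normalize its RMS to
    ``rms_target * 10**(-snr_db/20)``; add the two waveforms.

    With ``rms_scope="active_segments"`` (default) each component's RMS is
    taken over its own active intervals, so ``snr_db`` is exactly the
    speech-segment level re the noise-segment level; ``"whole"`` normalizes
    over the full file instead.
    """
    if sentence.sample_rate != model.sample_rate:
        raise ValueError("sentence and noise model sample rates differ")
    smap = make_segment_map(len(sentence), sentence.sample_rate, spec)
    speech = gate_signal(sentence, smap, spec.ramp_ms)
    speech = rms_normalize(speech, rms_target, rms_scope, smap)

    gap_map = smap.complement()
    if not gap_map.labelled("speech"):
        # degenerate duty == 1: no gaps to fill, noise is silence
        burst = speech
        noise = speech.replace_samples(np.zeros(len(speech)))
    else:
        noise_raw = synthesize_noise(model, len(sentence), seed)
        noise = gate_signal(noise_raw, gap_map, spec.ramp_ms)
        noise_target = rms_target * 10.0 ** (-snr_db / 20.0)
        noise = rms_normalize(noise, noise_target, rms_scope, gap_map)
        burst = speech.replace_samples(speech.samples + noise.samples)
    return StimulusPair(speech, burst, smap, snr_db)


def measure_snr_db(pair: StimulusPair) -> float:
    """Speech-minus-noise segment level of the noise-burst stimulus, in dB.

    20*log10 of the RMS over speech intervals divided by the RMS over gap
    (noise) intervals; for a pair built with ``snr_db = -10`` this measures
    -10 dB.
    """
    speech_mask = pair.segment_map.mask("speech")
    gap_mask = ~speech_mask
    if not gap_mask.any():
        raise ValueError("pair has no gap intervals; SNR undefined")
    return 20.0 * np.log10(
        rms(pair.noise_burst, speech_mask) / rms(pair.noise_burst, gap_mask)
    )
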