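"""Square-wave gating of sentence audio into speech/gap segments.

The interrupted-speech paradigm deletes speech periodically: a square wave at
``rate_hz`` with duty cycle ``duty`` selects which portions of the waveform
survive. At the defaults (2.0 Hz, 50% duty) a sentence becomes alternating
250 ms segments of speech and silence. Raised-cosine on/off ramps at each
surviving segment edge suppress the spectral splatter of abrupt gating.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio import AudioSignal

__all__ = ["GatingSpec", "SegmentMap", "make_segment_map", "gate_signal"]

SPEECH = "speech"
GAP = "gap"


@dataclass(frozen=True)
class GatingSpec:
    """Interruption parameters.

    rate_hz : interruption rate (full speech+gap periods per second).
    duty : fraction of each period that is speech, in (0, 1].
    start_phase : "speech_first" or "gap_first" — what the sentence opens with.
    ramp_ms : raised-cosine ramp duration at each speech-segment edge.
    """

    rate_hz: float = 2.0
    duty: float = 0.5
    start_phase: str = "speech_first"
    ramp_ms: float = 10.0

    def __post_init__(self) -> None:
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if not 0 < self.duty <= 1:
            raise ValueError("duty must be in (0, 1]")
        if self.start_phase not in ("speech_first", "gap_first"):
            raise ValueError("start_phase must be 'speech_first' or 'gap_first'")
        half = self.duty * 1000.0 / (2.0 * self.rate_hz)
        if not 0 <= self.ramp_ms <= half:
            raise ValueError(
                f"ramp_ms={self.ramp_ms} does not fit inside a "
                f"{2 * half:.1f} ms speech segment"
            )


@dataclass(frozen=True)
class SegmentMap:
    """Partition of [0, n_samples) into alternating speech/gap intervals.

    Intervals are half-open ``(start, end, label)`` triples in samples,
    0-based, tiling the signal with no overlap or hole.
    """

    intervals: tuple
    n_samples: int

    def __post_init__(self) -> None:
        ivs = tuple((int(s), int(e), str(lab)) for s, e, lab in self.intervals)
        if not ivs:
            raise ValueError("segment map must contain at least one interval")
        pos = 0
        prev_label = None
        for s, e, lab in ivs:
            if lab not in (SPEECH, GAP):
                raise ValueError(f"unknown label {lab!r}")
            if s != pos or e <= s:
                raise ValueError("intervals must tile [0, n) contiguously")
            if lab == prev_label:
                raise ValueError("labels must alternate")
            pos, prev_label = e, lab
        if pos != self.n_samples:
            raise ValueError("intervals do not cover n_samples")
        object.__setattr__(self, "intervals", ivs)
        object.__setattr__(self, "n_samples", int(self.n_samples))

    def mask(self, label: str = SPEECH) -> np.ndarray:
        """Boolean per-sample mask for one label."""
        m = np.zeros(self.n_samples, dtype=bool)
        for s, e, lab in self.intervals:
            if lab == label:
                m[s:e] = True
        return m

    def labelled(self, label: str) -> list:
        return [(s, e) for s, e, lab in self.intervals if lab == label]

    def complement(self) -> "SegmentMap":
        """Swap speech and gap labels (used to gate the noise to the gaps)."""
        swapped = tuple(
            (s, e, GAP if lab == SPEECH else SPEECH) for s, e, lab in self.intervals
        )
        return SegmentMap(swapped, self.n_samples)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["start_sample", "end_sample", "label"])
            w.writerows(self.intervals)

    @classmethod
    def from_csv(cls, path) -> "SegmentMap":
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append((int(rec["start_sample"]), int(rec["end_sample"]), rec["label"]))
        return cls(tuple(rows), rows[-1][1])


def make_segment_map(n_samples: int, sample_rate: float, spec: GatingSpec) -> SegmentMap:
    """Lay out alternating speech/gap intervals for a square-wave gate.

    Boundaries fall at multiples of the (duty-split) period, rounded to the
    nearest sample; the final partial segment is truncated at ``n_samples``.
    With ``duty == 1`` the map degenerates to a single speech interval.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    period = sample_rate / spec.rate_hz
    if spec.start_phase == "speech_first":
        pattern = ((SPEECH, spec.duty), (GAP, 1.0 - spec.duty))
    else:
        pattern = ((GAP, 1.0 - spec.duty), (SPEECH, spec.duty))

    intervals = []
    k = 0
    t = 0.0  # exact boundary time in samples, rounded only at emission
    while True:
        for label, frac in pattern:
            if frac <= 0.0:
                continue
            start = int(round(t))
            t += frac * period
            end = min(int(round(t)), n_samples)
            if end > start:
                if intervals and intervals[-1][2] == label:
                    # merge (can occur when a zero-length partner was skipped)
                    s0, _, _ = intervals[-1]
                    intervals[-1] = (s0, end, label)
                else:
                    intervals.append((start, end, label))
            if end >= n_samples:
                return SegmentMap(tuple(intervals), n_samples)
        k += 1


def _ramp_profile(n: int) -> np.ndarray:
    """Rising raised-cosine 0.5*(1 - cos(pi*t/T)) sampled at t = i*T/n."""
    i = np.arange(n, dtype=float)
    return 0.5 * (1.0 - np.cos(np.pi * i / n))


def gating_envelope(segment_map: SegmentMap, sample_rate: float, ramp_ms: float) -> np.ndarray:
    """Per-sample gain: 0 on gaps, 1 on speech, raised-cosine at speech edges.

    Ramps must fit inside every full-length speech segment (half the segment
    each); the sentence-final truncated segment gets a shortened ramp.
    """
    n_ramp = int(round(ramp_ms * sample_rate / 1000.0))
    env = np.zeros(segment_map.n_samples)
    speech = segment_map.labelled(SPEECH)
    if not speech:
        return env
    full_len = max(e - s for s, e in speech)
    for idx, (s, e) in enumerate(speech):
        seg_len = e - s
        r = n_ramp
        if seg_len < full_len or seg_len < 2 * n_ramp:
            if idx == len(speech) - 1 or seg_len == segment_map.n_samples:
                r = min(n_ramp, seg_len // 2)  # truncated final segment
            elif 2 * n_ramp > seg_len:
                raise ValueError(
                    f"ramp of {n_ramp} samples does not fit in a "
                    f"{seg_len}-sample speech segment"
                )
        env[s:e] = 1.0
        if r > 0:
            profile = _ramp_profile(r)
            env[s : s + r] = profile
            env[e - r : e] = profile[::-1]
    return env


def gate_signal(signal: AudioSignal, segment_map: SegmentMap, ramp_ms: float = 10.0) -> AudioSignal:
    """Apply the gate: zero the gaps, keep speech, ramp the speech edges.

    Gap samples are exactly zero; speech samples equal the input except
    within the first/last ``ramp_ms`` of each speech interval, where they are
    scaled by the raised cosine 0.5*(1 - cos(pi*t/T)) (rising; mirrored when
    falling). Output length equals input length.
    """
    if segment_map.n_samples != len(signal):
        raise ValueError(
            f"segment map covers {segment_map.n_samples} samples, "
            f"signal has {len(signal)}"
        )
    env = gating_envelope(segment_map, signal.sample_rate, ramp_ms)
    return signal.replace_samples(signal.samples * env)
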