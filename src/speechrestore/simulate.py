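"""Synthetic study data with known ground truth.

Three generators make every pipeline stage testable without the original
recordings or participant data:

* :func:`synth_sentence` — a formant-synthesizer stand-in for sentence
  audio: a harmonic pulse train at ``f0`` shaped by parallel two-pole
  formant resonators and amplitude-modulated by a raised-cosine syllabic
  envelope. It has speech-like spectra and envelopes, which is what the
  stimulus DSP needs; it is not intelligible speech.
* :func:`simulate_cohort` — participants whose six condition scores are a
  linear function of four latent abilities (working memory, inhibitory
  control, processing speed, lexical knowledge) plus Gaussian noise, with
  observed task measures produced from the latents by fixed affine maps.
  The default condition means/SDs, effect sizes and ability correlations
  are the study conditions the statistical pipeline is meant to recover.
* :func:`simulate_transcripts` — typed responses in which each keyword is
  reported with probability ``p_report`` and, when reported, corrupted with
  probability ``p_typo`` by exactly one scorer-covered typo, so the scored
  percent depends only on ``p_report`` (generator-scorer closure).

All generators are deterministic for a fixed seed; sub-seeds are derived by
stable hashing so corpus order never changes outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .audio import AudioSignal, rms_normalize
from .autoscore import KeywordList

__all__ = [
    "SentenceSpec",
    "CohortSpec",
    "derive_seed",
    "synth_sentence",
    "simulate_cohort",
    "simulate_transcripts",
    "simulate_trial_logs",
    "synthetic_dst_norms",
    "CONDITIONS",
    "ABILITIES",
    "DEFAULT_CONDITION_MEANS",
    "DEFAULT_BETAS",
    "SCREEN_COLUMNS",
]

CONDITIONS = [
    "rspin_high_silent",
    "rspin_high_noise",
    "rspin_low_silent",
    "rspin_low_noise",
    "presto_silent",
    "presto_noise",
]

ABILITIES = ["rst", "stroop_interference", "stroop_speed", "lextale"]

# Per-condition mean percent correct of the emulated cohort.
DEFAULT_CONDITION_MEANS = {
    "rspin_high_silent": 48.3,
    "rspin_high_noise": 60.1,
    "rspin_low_silent": 42.4,
    "rspin_low_noise": 50.4,
    "presto_silent": 27.6,
    "presto_noise": 43.1,
}

# Effect of one SD of each latent ability on each condition score (percent).
DEFAULT_BETAS = {
    "rspin_high_silent": [3.01, -0.66, -1.21, 2.40],
    "rspin_high_noise": [3.51, -1.42, -0.69, 0.47],
    "rspin_low_silent": [0.76, -1.45, -1.67, 1.47],
    "rspin_low_noise": [2.28, -2.09, -1.35, 0.34],
    "presto_silent": [2.16, -0.18, -2.48, 2.48],
    "presto_noise": [2.98, -2.17, -1.74, 1.55],
}

# Weak latent intercorrelations, as observed among the four predictors.
DEFAULT_ABILITY_CORR = np.array([
    [1.00, 0.005, -0.15, 0.04],
    [0.005, 1.00, -0.07, -0.19],
    [-0.15, -0.07, 1.00, -0.13],
    [0.04, -0.19, -0.13, 1.00],
])

# Affine latent -> observed maps: (column, mean, sd, clip_lo, clip_hi)
_MEASURE_MAPS = {
    "rst": ("rst_percent", 73.5, 14.3, 0.0, 100.0),
    "stroop_interference": ("stroop_interference", 1.35, 0.26, 0.5, None),
    "stroop_speed": ("stroop_speed_ms", 804.9, 156.9, 300.0, None),
    "lextale": ("lextale_percent", 88.7, 9.4, 0.0, 100.0),
}

# The 17 measures entering the default outlier screen: 13 experimental
# measures plus age and the three self-report hearing domains.
SCREEN_COLUMNS = [
    "rst_percent", "dst_percentile", "stroop_interference", "stroop_speed_ms",
    "flanker_interference_ms", "lextale_percent", "lextale_word_rt_ms",
] + CONDITIONS + ["age", "ssq_speech", "ssq_spatial", "ssq_qualities"]

_WORDS = (
    "ball bounce table garden window stream candle marble ribbon copper "
    "valley thunder meadow basket lantern pepper timber harbor saddle "
    "mirror walnut anchor barrel carpet dolphin engine feather goblet "
    "hammer island jacket kettle ladder magnet needle orchard puzzle "
    "quiver rocket shovel trumpet velvet wagon yellow zipper attic "
    "bridge cellar don't can't won't it's blossom crystal dragon ember "
    "forest glacier horizon insect jungle kitten lemon monkey nutmeg "
    "ocean pencil quartz river sunset tunnel umbrella violin whistle "
    "autumn butter camera desert eagle fabric grape helmet ivory jewel "
    "kayak lizard mountain napkin onion parrot quilt rabbit spider tiger "
    "urchin vessel walrus xylophone yogurt zebra apple bottle circle "
    "doctor elephant finger guitar hunter igloo silver keeper lumber"
).split()


def derive_seed(master: int, *labels) -> int:
    """Stable sub-seed from a master seed and a label path (< 2^31)."""
    key = repr((int(master),) + tuple(str(x) for x in labels)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class SentenceSpec:
    """Parameters of one synthetic sentence."""

    duration_s: float = 2.0
    f0_hz: float = 100.0
    formants_hz: tuple = (500.0, 1500.0, 2500.0)
    syllable_rate_hz: float = 4.0
    sample_rate: float = 16000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.syllable_rate_hz > 0:
            raise ValueError("syllable_rate_hz must be positive")
        nyquist = self.sample_rate / 2.0
        if not self.formants_hz or not (
            self.f0_hz < min(self.formants_hz) and max(self.formants_hz) < nyquist
        ):
            raise ValueError("need f0 < min formant < ... < Nyquist")


def synth_sentence(spec: SentenceSpec):
    """Synthesize one sentence stand-in and its pseudo-keywords.

    Returns ``(AudioSignal, KeywordList)``; bit-identical for a fixed seed.
    """
    fs = spec.sample_rate
    n = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed)

    # glottal pulse train at f0 with slight jitter for a natural spectrum
    period = fs / spec.f0_hz
    source = np.zeros(n)
    t = 0.0
    while t < n:
        idx = int(round(t))
        if idx < n:
            source[idx] = 1.0
        t += period * (1.0 + 0.002 * rng.standard_normal())

    # parallel two-pole resonators at the formant frequencies
    out = np.zeros(n)
    for f in spec.formants_hz:
        bw = 80.0 + 0.04 * f  # bandwidth widens with frequency
        r = np.exp(-np.pi * bw / fs)
        a = [1.0, -2.0 * r * np.cos(2.0 * np.pi * f / fs), r * r]
        out += spsig.lfilter([1.0 - r], a, source)

    # raised-cosine syllabic envelope + sentence-edge taper
    tt = np.arange(n) / fs
    syllabic = 0.15 + 0.85 * 0.5 * (1.0 - np.cos(2.0 * np.pi * spec.syllable_rate_hz * tt))
    edge = np.minimum(1.0, np.minimum(tt, tt[::-1]) / 0.05)
    samples = out * syllabic * edge
    audio = rms_normalize(AudioSignal(samples, fs), 0.05)

    n_words = int(rng.integers(4, 6))  # 4-5 content words per sentence
    kws = tuple(rng.choice(_WORDS, size=n_words, replace=False))
    return audio, KeywordList(f"s{spec.seed}", kws)


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a participant cohort."""

    n: int = 63
    ability_names: tuple = tuple(ABILITIES)
    ability_corr: np.ndarray = field(default_factory=lambda: DEFAULT_ABILITY_CORR.copy())
    condition_means: dict = field(default_factory=lambda: dict(DEFAULT_CONDITION_MEANS))
    betas: dict = field(default_factory=lambda: {c: list(v) for c, v in DEFAULT_BETAS.items()})
    residual_sd: float = 7.5
    seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.ability_corr, float)
        k = len(self.ability_names)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T):
            raise ValueError("ability_corr must be a symmetric k x k matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("ability_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("ability_corr must be positive-definite")
        if not self.residual_sd > 0:
            raise ValueError("residual_sd must be positive")
        for c, m in self.condition_means.items():
            if not 0 <= m <= 100:
                raise ValueError(f"condition mean out of [0, 100]: {c}")
        object.__setattr__(self, "ability_corr", corr)


def _clip(x, lo, hi):
    if lo is not None:
        x = np.maximum(x, lo)
    if hi is not None:
        x = np.minimum(x, hi)
    return x


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort; returns one row per participant.

    Columns: ``z_<ability>`` latent truths, the seven observed task
    measures, demographics/self-report, and the six condition scores
    (condition mean + sum of beta * latent + Gaussian residual, clipped to
    [0, 100]). Indexed by participant_id.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.ability_names)
    L = np.linalg.cholesky(spec.ability_corr)
    z = rng.standard_normal((spec.n, k)) @ L.T

    df = pd.DataFrame(index=[f"p{i:03d}" for i in range(spec.n)])
    df.index.name = "participant_id"
    for j, name in enumerate(spec.ability_names):
        df[f"z_{name}"] = z[:, j]

    for name in spec.ability_names:
        col, mu, sd, lo, hi = _MEASURE_MAPS[name]
        df[col] = _clip(mu + sd * df[f"z_{name}"].to_numpy(), lo, hi)

    # secondary measures: latents correlated with the core four
    z_rst = df["z_rst"].to_numpy() if "z_rst" in df else z[:, 0]
    e = rng.standard_normal((spec.n, 3))
    z_dst = 0.28 * z_rst + np.sqrt(1 - 0.28**2) * e[:, 0]
    z_flank = -0.28 * z_rst + np.sqrt(1 - 0.28**2) * e[:, 1]
    zi = df.get("z_stroop_interference", pd.Series(z[:, 1], index=df.index)).to_numpy()
    zs = df.get("z_stroop_speed", pd.Series(z[:, 2], index=df.index)).to_numpy()
    z_lexrt = 0.29 * zi + 0.29 * zs + np.sqrt(1 - 2 * 0.29**2) * e[:, 2]
    df["dst_percentile"] = _clip(72.6 + 28.6 * z_dst, 0.1, 99.9)
    df["flanker_interference_ms"] = 41.0 + 23.7 * z_flank
    df["lextale_word_rt_ms"] = _clip(754.3 + 125.5 * z_lexrt, 300.0, None)

    # demographics and self-report, independent of the abilities
    df["age"] = np.clip(np.round(42.0 + 12.0 * rng.standard_normal(spec.n)), 22, 63)
    df["education"] = np.clip(np.round(15.4 + 2.8 * rng.standard_normal(spec.n)), 8, 24)
    df["ssq_speech"] = _clip(8.4 + 1.4 * rng.standard_normal(spec.n), 0, 10)
    df["ssq_spatial"] = _clip(7.7 + 1.5 * rng.standard_normal(spec.n), 0, 10)
    df["ssq_qualities"] = _clip(8.6 + 1.2 * rng.standard_normal(spec.n), 0, 10)

    beta = np.array([spec.betas[c] for c in spec.condition_means], float)
    for i, cond in enumerate(spec.condition_means):
        eps = rng.normal(0.0, spec.residual_sd, spec.n)
        score = spec.condition_means[cond] + z @ beta[i] + eps
        df[cond] = np.clip(score, 0.0, 100.0)
    return df


def _apply_typo(keyword: str, rng: np.random.Generator) -> str:
    """One scorer-covered corruption of a keyword."""
    doubles = [i for i in range(len(keyword) - 1) if keyword[i] == keyword[i + 1]]
    swaps = [i for i in range(len(keyword) - 1) if keyword[i] != keyword[i + 1]]
    ops = []
    if doubles:
        ops.append("double")
    if swaps:
        ops.append("swap")
    if "'" in keyword:
        ops.append("drop_apostrophe")
    else:
        ops.append("insert_apostrophe")
    op = ops[int(rng.integers(len(ops)))]
    if op == "double":
        i = doubles[int(rng.integers(len(doubles)))]
        return keyword[:i] + keyword[i + 1 :]
    if op == "swap":
        i = swaps[int(rng.integers(len(swaps)))]
        return keyword[:i] + keyword[i + 1] + keyword[i] + keyword[i + 2 :]
    if op == "drop_apostrophe":
        i = keyword.index("'")
        return keyword[:i] + keyword[i + 1 :]
    i = int(rng.integers(1, len(keyword)))
    return keyword[:i] + "'" + keyword[i:]


def simulate_transcripts(
    keyword_lists,
    p_report: float,
    p_typo: float,
    seed: int,
    participant_id: str = "p000",
) -> pd.DataFrame:
    """Typed responses for one participant over a sentence list.

    Every keyword is independently reported with probability ``p_report``;
    a reported keyword is corrupted with probability ``p_typo`` by exactly
    one rule-covered typo. Deterministic for a fixed seed.
    """
    if not 0 <= p_report <= 1 or not 0 <= p_typo <= 1:
        raise ValueError("probabilities must be in [0, 1]")
    rows = []
    for kl in keyword_lists:
        rng = np.random.default_rng(derive_seed(seed, participant_id, kl.sentence_id))
        words = []
        for kw in kl.keywords:
            if rng.random() < p_report:
                words.append(_apply_typo(kw, rng) if rng.random() < p_typo else kw)
        rows.append({
            "participant_id": participant_id,
            "sentence_id": kl.sentence_id,
            "transcript": " ".join(words),
        })
    return pd.DataFrame(rows)


def synthetic_dst_norms() -> dict:
    """Synthetic digit-span normative table (total correct -> percentile).

    A smooth logistic stand-in for published norms, centered so that a
    total of 14/28 maps near the 50th percentile. Synthetic: for simulation
    and testing only, not a reproduction of any published normative data.
    """
    totals = np.arange(0, 29)
    pct = 100.0 / (1.0 + np.exp(-(totals - 13.0) / 2.6))
    pct = np.clip(pct, 0.1, 99.9)
    return {int(t): float(p) for t, p in zip(totals, pct)}


def _norm_inverse(table: dict, percentile: float) -> int:
    """Total whose normative percentile is closest to the requested one."""
    return min(table, key=lambda t: abs(table[t] - percentile))


def simulate_trial_logs(measures: pd.DataFrame, seed: int, norms: dict | None = None) -> pd.DataFrame:
    """Trial-level logs whose scoring reproduces the cohort's measures.

    For each participant the generator emits reading-span sequences, digit
    span trials honoring the stop rule, Stroop/Flanker RT trials with exact
    condition means, and a 40-word/20-nonword lexical decision run, such
    that the task scorers recover the measure-table values up to item-count
    granularity.
    """
    norms = norms or synthetic_dst_norms()
    rows = []
    for pid, m in measures.iterrows():
        rng = np.random.default_rng(derive_seed(seed, "trials", pid))

        # --- reading span: 10 sequences x 3 targets -----------------------
        n_seq, per_seq = 10, 3
        total = n_seq * per_seq
        n_recalled = int(round(m["rst_percent"] * total / 100.0))
        words = list(rng.choice(_WORDS, size=total, replace=False))
        recalled_flags = np.zeros(total, bool)
        recalled_flags[rng.choice(total, size=n_recalled, replace=False)] = True
        for s in range(n_seq):
            targets = words[s * per_seq : (s + 1) * per_seq]
            flags = recalled_flags[s * per_seq : (s + 1) * per_seq]
            typed = [w for w, f in zip(targets, flags) if f]
            rng.shuffle(typed)  # recall order never matters
            rows.append(_trial(pid, "rst", f"seq{s}", ";".join(targets),
                               " ".join(typed), bool(all(flags)), 0.0))

        # --- digit span: lengths 3..9, two trials per length --------------
        target_total = _norm_inverse(norms, float(m["dst_percentile"]))
        fwd = min(14, (target_total + 1) // 2)
        bwd = target_total - fwd
        for direction, quota in (("forward", fwd), ("backward", bwd)):
            done = 0
            for length in range(3, 10):
                hits = min(2, quota - done)
                for trial in (1, 2):
                    ok = trial <= hits
                    digits = "".join(map(str, rng.integers(0, 10, length)))
                    resp = digits if ok else digits[::-1] + "9"
                    rows.append(_trial(pid, "dst", f"{length}_{trial}", direction,
                                       resp, ok, 1000.0 + 50 * length))
                done += hits
                if hits == 0:
                    break  # both wrong: the task ends

        # --- stroop: 25 items per condition, exact means ------------------
        c_mean = m["stroop_speed_ms"] * 0.9
        means = {"W": m["stroop_speed_ms"], "C": c_mean,
                 "CW": m["stroop_interference"] * c_mean}
        for cond, mu in means.items():
            rts = _exact_mean_rts(rng, 25, mu, 60.0)
            for i, rt in enumerate(rts):
                rows.append(_trial(pid, "stroop", f"{cond.lower()}{i}", cond, cond, True, rt))

        # --- flanker: 45 congruent + 45 incongruent, exact means ----------
        base = 480.0
        for cond, mu in (("congruent", base), ("incongruent", base + m["flanker_interference_ms"])):
            rts = _exact_mean_rts(rng, 45, mu, 50.0)
            for i, rt in enumerate(rts):
                rows.append(_trial(pid, "flanker", f"{cond[:3]}{i}", cond, "<", True, rt))

        # --- lexical decision: 40 words + 20 nonwords ---------------------
        w_ok = int(round(m["lextale_percent"] * 40 / 100.0))
        nw_ok = int(round(m["lextale_percent"] * 20 / 100.0))
        word_rts = _exact_mean_rts(rng, max(w_ok, 1), m["lextale_word_rt_ms"], 80.0, cap=1999.0)
        wi = 0
        for cls, n_items, n_hit in (("word", 40, w_ok), ("nonword", 20, nw_ok)):
            for i in range(n_items):
                ok = i < n_hit
                if cls == "word" and ok:
                    rt = word_rts[wi]
                    wi += 1
                else:
                    rt = float(rng.uniform(600, 1500))
                timeout = not ok and rng.random() < 0.3
                rows.append(_trial(pid, "lextale", f"{cls}{i}", cls,
                                   "j" if cls == "word" else "k", ok, rt, timeout))
    return pd.DataFrame(rows)


def _trial(pid, task, item, cond, resp, ok, rt, timeout=False):
    return {
        "participant_id": pid, "task": task, "item_id": item, "condition": cond,
        "response": resp, "correct": bool(ok), "rt_ms": float(rt), "timeout": bool(timeout),
    }


def _exact_mean_rts(rng, n, mean, sd, cap=None):
    """n positive RTs with the exact requested mean."""
    x = rng.normal(0.0, sd, n)
    x -= x.mean()
    rts = np.maximum(mean + x, 120.0)
    rts += mean - rts.mean()  # re-center after the floor
    if cap is not None:
        rts = np.minimum(rts, cap)
        rts += mean - rts.mean()
    return rts
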