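"""Scoring of the cognitive and linguistic task battery from trial-level logs.

Seven measures are derived from four cognitive tasks and one linguistic task:

* **RST percent correct** — reading span; percent of first/last content
  words recalled in any order (complex working memory capacity).
* **DST percentile** — digit span forward + backward total correct, mapped
  through a user-supplied normative table (simple working memory).
* **Stroop interference** — mean correct RT on incongruent color-word (CW)
  items divided by mean correct RT on color-only (C) items (inhibitory
  control; ratio > 1 means interference).
* **Stroop processing speed (ms)** — mean correct RT naming color words (W).
* **Flanker interference (ms)** — mean correct incongruent RT minus mean
  correct congruent RT (may be negative).
* **LexTALE percent correct** — class-balanced average of real-word and
  non-word accuracy (lexical knowledge); timeouts count as incorrect.
* **LexTALE word RT (ms)** — mean RT over correct, non-timeout real words
  (lexical access speed).

Trial logs are long-format records: one row per item (RST: one row per
recall sequence) with task, condition, response, correctness, RT and a
timeout flag. No RT outlier trimming is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MeasureSet",
    "score_rst",
    "score_digit_span",
    "score_stroop",
    "score_flanker",
    "score_lextale",
    "score_participant",
    "score_trial_log",
    "read_norms_csv",
    "MEASURE_COLUMNS",
]

MEASURE_COLUMNS = [
    "rst_percent",
    "dst_percentile",
    "stroop_interference",
    "stroop_speed_ms",
    "flanker_interference_ms",
    "lextale_percent",
    "lextale_word_rt_ms",
]


class UndefinedMeasureError(ValueError):
    """A measure's defining cells are empty (e.g., no correct C trials)."""


@dataclass(frozen=True)
class MeasureSet:
    """One participant's seven cognitive/linguistic scores."""

    rst_percent: float
    dst_percentile: Optional[float]
    dst_total: int
    stroop_interference: float
    stroop_speed_ms: float
    flanker_interference_ms: float
    lextale_percent: float
    lextale_word_rt_ms: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in MEASURE_COLUMNS}


def _as_bool(series: pd.Series) -> np.ndarray:
    if series.dtype == bool:
        return series.to_numpy()
    return (
        series.astype(str).str.strip().str.lower().isin(["true", "1", "yes"])
    ).to_numpy()


def score_rst(trials: pd.DataFrame) -> float:
    """Percent of reading-span target words recalled, in any order.

    Each row is one recall sequence: ``condition`` holds the target words
    joined by ``;`` and ``response`` the participant's typed recall. A target
    is credited when it appears among the typed words (case-insensitive,
    exact spelling); each typed word can credit only one target.
    """
    total = 0
    recalled = 0
    for _, row in trials.iterrows():
        targets = [t.strip().lower() for t in str(row["condition"]).split(";") if t.strip()]
        typed = str(row.get("response", "")).lower().split()
        total += len(targets)
        pool = list(typed)
        for t in targets:
            if t in pool:
                pool.remove(t)
                recalled += 1
    if total == 0:
        raise UndefinedMeasureError("reading span log contains no target words")
    return 100.0 * recalled / total


def _span_correct(trials: pd.DataFrame) -> int:
    """Correct digit-span trials honoring the two-wrong stop rule."""
    df = trials.copy()
    df["_length"] = [int(str(i).split("_")[0]) for i in df["item_id"]]
    df = df.sort_values(["_length", "item_id"], kind="stable")
    correct = 0
    for length, grp in df.groupby("_length", sort=True):
        ok = _as_bool(grp["correct"])
        correct += int(ok.sum())
        if len(ok) >= 2 and not ok.any():
            break  # both trials wrong: the task would have ended here
    return correct


def score_digit_span(trials: pd.DataFrame, norm_table: Optional[dict] = None):
    """(total_correct, percentile) for digit span forward + backward.

    Trials carry ``condition`` in {forward, backward} and ``item_id`` of the
    form ``<length>_<trial>`` with two trials per sequence length. Per
    direction, scoring stops after the first length where both trials are
    wrong. The percentile is the normative lookup of the combined total;
    without a table it is None (absent, not zero).
    """
    total = 0
    for direction in ("forward", "backward"):
        sub = trials[trials["condition"] == direction]
        if not sub.empty:
            total += _span_correct(sub)
    if norm_table is None:
        return total, None
    if total not in norm_table:
        raise KeyError(f"norm table has no entry for total_correct={total}")
    return total, float(norm_table[total])


def _mean_rt(trials: pd.DataFrame, condition: str, task: str) -> float:
    sub = trials[(trials["condition"] == condition) & _as_bool(trials["correct"])]
    if sub.empty:
        raise UndefinedMeasureError(f"no correct {condition} trials for {task}")
    return float(sub["rt_ms"].astype(float).mean())


def score_stroop(trials: pd.DataFrame):
    """(interference CW/C, processing speed = mean correct W RT in ms)."""
    speed = _mean_rt(trials, "W", "stroop")
    interference = _mean_rt(trials, "CW", "stroop") / _mean_rt(trials, "C", "stroop")
    return interference, speed


def score_flanker(trials: pd.DataFrame) -> float:
    """Mean correct incongruent RT minus mean correct congruent RT (ms)."""
    return _mean_rt(trials, "incongruent", "flanker") - _mean_rt(
        trials, "congruent", "flanker"
    )


def score_lextale(trials: pd.DataFrame):
    """(class-balanced percent correct, mean correct real-word RT in ms).

    Timeouts are scored incorrect. Accuracy averages the word and non-word
    percentages, so the 40/20 item imbalance does not weight real words
    double. RT pools correct, non-timeout real words only.
    """
    df = trials.copy()
    ok = _as_bool(df["correct"]) & ~_as_bool(df["timeout"])
    out = {}
    for cls in ("word", "nonword"):
        mask = (df["condition"] == cls).to_numpy()
        n = int(mask.sum())
        if n == 0:
            raise UndefinedMeasureError(f"lexical decision log has no {cls} items")
        out[cls] = 100.0 * ok[mask].sum() / n
    percent = (out["word"] + out["nonword"]) / 2.0
    words_ok = df[(df["condition"] == "word").to_numpy() & ok]
    if words_ok.empty:
        raise UndefinedMeasureError("no correctly identified real words; RT undefined")
    return percent, float(words_ok["rt_ms"].astype(float).mean())


def score_participant(trials: pd.DataFrame, norm_table: Optional[dict] = None) -> MeasureSet:
    """Compute all seven measures from one participant's trial log."""
    by_task = {task: grp for task, grp in trials.groupby("task")}
    for task in ("rst", "dst", "stroop", "flanker", "lextale"):
        if task not in by_task:
            raise UndefinedMeasureError(f"trial log is missing task {task!r}")
    rst = score_rst(by_task["rst"])
    dst_total, dst_pct = score_digit_span(by_task["dst"], norm_table)
    interference, speed = score_stroop(by_task["stroop"])
    flanker = score_flanker(by_task["flanker"])
    lex_pct, lex_rt = score_lextale(by_task["lextale"])
    return MeasureSet(rst, dst_pct, dst_total, interference, speed, flanker, lex_pct, lex_rt)


def score_trial_log(trials: pd.DataFrame, norm_table: Optional[dict] = None) -> pd.DataFrame:
    """Score every participant in a long trial log; one row per participant."""
    rows = []
    for pid, grp in trials.groupby("participant_id"):
        ms = score_participant(grp, norm_table)
        rows.append({"participant_id": pid, **ms.as_dict()})
    return pd.DataFrame(rows).set_index("participant_id")


def read_norms_csv(path) -> dict:
    """Read a `total_correct,percentile` normative lookup table."""
    df = pd.read_csv(path)
    if not {"total_correct", "percentile"}.issubset(df.columns):
        raise ValueError("norms CSV needs columns total_correct,percentile")
    table = dict(zip(df["total_correct"].astype(int), df["percentile"].astype(float)))
    totals = sorted(table)
    values = [table[t] for t in totals]
    if any(b < a for a, b in zip(values, values[1:])):
        raise ValueError("norm table must be monotone in total_correct")
    return table
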