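"""Keyword autoscoring of typed transcripts.

Each sentence has a list of content-word keywords; a participant's typed
response is scored by counting how many keywords appear in it, under a
deliberately strict tolerance for typing slips:

* **double letter** — a doubled letter omitted within a word ("atack" is
  accepted for "attack");
* **transposition** — exactly one adjacent-letter swap ("tkae" for "take");
* **apostrophe** — one apostrophe inserted or omitted ("dont" for "don't");
* **custom spellings** — an explicit per-keyword list of accepted variants.

Exactly one rule application per token, no chaining. Matching is a bag
(order-independent) assignment: each transcript token can satisfy at most
one keyword, resolved as a maximum bipartite matching so duplicated
keywords are never over-credited.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

__all__ = [
    "KeywordList",
    "ScoringRules",
    "ScoreResult",
    "normalize_transcript",
    "keyword_matches",
    "rule_variants",
    "score_response",
    "aggregate_condition",
    "read_keywords_csv",
    "read_transcripts_csv",
]

_TOKEN_RE = re.compile(r"[a-z']+")


@dataclass(frozen=True)
class KeywordList:
    """Ordered content-word keywords of one sentence."""

    sentence_id: str
    keywords: tuple

    def __post_init__(self) -> None:
        kws = tuple(str(k) for k in self.keywords)
        if not kws:
            raise ValueError("keyword list must be nonempty")
        for k in kws:
            if not re.fullmatch(r"[a-z']+", k):
                raise ValueError(f"keyword {k!r} must be lowercase letters/apostrophes")
        object.__setattr__(self, "keywords", kws)
        object.__setattr__(self, "sentence_id", str(self.sentence_id))


@dataclass(frozen=True)
class ScoringRules:
    """Which tolerance rules are active; defaults mirror the strict set."""

    double_letter: bool = True
    transposition: bool = True
    apostrophe: bool = True
    collapse_double_space: bool = True
    custom_spellings: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of scoring one response against one keyword list."""

    sentence_id: str
    n_keywords: int
    n_correct: int
    matched: tuple  # (keyword, transcript token) pairs, injective over tokens

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_keywords:
            raise ValueError("n_correct out of range")


def normalize_transcript(text: str) -> list:
    """Lowercase, collapse whitespace, strip punctuation except inner apostrophes.

    Hyphens and digits are stripped (hyphens split words); leading/trailing
    apostrophes are removed so quoting cannot defeat matching. Empty input
    yields an empty list.
    """
    text = str(text).lower().replace("-", " ")
    tokens = []
    for raw in _TOKEN_RE.findall(text):
        tok = raw.strip("'")
        if tok:
            tokens.append(tok)
    return tokens


def rule_variants(keyword: str, rules: ScoringRules) -> set:
    """All tokens accepted for ``keyword`` under one rule application."""
    variants = {keyword}
    if rules.double_letter:
        for i in range(len(keyword) - 1):
            if keyword[i] == keyword[i + 1]:
                variants.add(keyword[:i] + keyword[i + 1 :])
    if rules.transposition:
        for i in range(len(keyword) - 1):
            swapped = (
                keyword[:i] + keyword[i + 1] + keyword[i] + keyword[i + 2 :]
            )
            variants.add(swapped)
    if rules.apostrophe:
        for i, ch in enumerate(keyword):
            if ch == "'":
                variants.add(keyword[:i] + keyword[i + 1 :])
        for i in range(1, len(keyword)):
            variants.add(keyword[:i] + "'" + keyword[i:])
    variants.update(rules.custom_spellings.get(keyword, ()))
    return variants


def keyword_matches(keyword: str, candidate: str, rules: ScoringRules) -> bool:
    """True iff ``candidate`` is accepted for ``keyword`` under the rules."""
    if candidate == keyword:
        return True
    return candidate in rule_variants(keyword, rules)


def score_response(
    keywords: KeywordList, transcript: str, rules: ScoringRules | None = None
) -> ScoreResult:
    """Score one typed response against one sentence's keywords.

    Tokens are consumed at most once; the assignment maximizes the number of
    matched keywords (maximum bipartite matching), so order never matters
    and repeated keywords require repeated tokens.
    """
    rules = rules or ScoringRules()
    for key in rules.custom_spellings:
        if key not in keywords.keywords:
            warnings.warn(
                f"custom spelling for {key!r} matches no keyword of "
                f"sentence {keywords.sentence_id}",
                stacklevel=2,
            )
    tokens = normalize_transcript(transcript)
    if not tokens:
        return ScoreResult(keywords.sentence_id, len(keywords.keywords), 0, ())
    adjacency = np.zeros((len(keywords.keywords), len(tokens)), dtype=bool)
    for i, kw in enumerate(keywords.keywords):
        accepted = rule_variants(kw, rules)
        for j, tok in enumerate(tokens):
            adjacency[i, j] = tok in accepted
    match = maximum_bipartite_matching(csr_matrix(adjacency), perm_type="column")
    pairs = tuple(
        (keywords.keywords[i], tokens[int(match[i])])
        for i in range(len(keywords.keywords))
        if match[i] >= 0
    )
    return ScoreResult(keywords.sentence_id, len(keywords.keywords), len(pairs), pairs)


def aggregate_condition(
    results, design: dict, conditions=None, method: str = "pooled"
) -> dict:
    """Percent of keywords correct per condition.

    ``design`` maps sentence_id -> condition label. ``method="pooled"``
    (default) computes 100 * sum(n_correct) / sum(n_keywords) over the
    condition's sentences; ``"mean"`` averages per-sentence percentages.
    Every scored sentence must be mapped, and every expected condition must
    receive at least one sentence.
    """
    results = list(results)
    buckets: dict = {}
    for res in results:
        if res.sentence_id not in design:
            raise KeyError(f"sentence {res.sentence_id!r} has no condition in design")
        buckets.setdefault(design[res.sentence_id], []).append(res)
    expected = set(conditions) if conditions is not None else set(buckets)
    missing = expected - set(buckets)
    if missing or not expected:
        raise ValueError(f"conditions with no scored sentences: {sorted(missing)}")
    out = {}
    for cond in sorted(expected):
        group = buckets[cond]
        if method == "pooled":
            out[cond] = 100.0 * sum(r.n_correct for r in group) / sum(
                r.n_keywords for r in group
            )
        elif method == "mean":
            out[cond] = float(
                np.mean([100.0 * r.n_correct / r.n_keywords for r in group])
            )
        else:
            raise ValueError(f"unknown aggregation method {method!r}")
    return out


def read_keywords_csv(path):
    """Read `sentence_id,condition,keyword_1..keyword_k` (ragged allowed).

    Returns (list of KeywordList, design dict sentence_id -> condition).
    """
    lists, design = [], {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["sentence_id", "condition"]:
            raise ValueError("keywords CSV must start with sentence_id,condition")
        for row in reader:
            if not row:
                continue
            sid, cond, *kws = row
            kws = [k.strip().lower() for k in kws if k.strip()]
            lists.append(KeywordList(sid, tuple(kws)))
            design[sid] = cond
    return lists, design


def read_transcripts_csv(path) -> pd.DataFrame:
    """Read `participant_id,sentence_id,transcript` into a DataFrame."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"participant_id", "sentence_id", "transcript"}
    if not required.issubset(df.columns):
        raise ValueError(f"transcripts CSV needs columns {sorted(required)}")
    return df
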