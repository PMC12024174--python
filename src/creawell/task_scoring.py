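"""Scoring of the behavioural creativity measures.

Alternate Uses Task (AUT): participants list unusual uses for three common
objects (bucket, comb, belt). Three indices are derived:

* **fluency** — the average number of valid responses across the three items;
* **overall originality** — 1 minus the participant's average sample-relative
  frequency of their uses, computed per item (sum of the relative frequencies
  of the participant's uses divided by that item's response count, subtracted
  from 1) and then averaged over the items that have responses;
* **peak originality** — the count, totalled over the three items, of uses
  produced by 10% or less of the sample (threshold inclusive).

The relative frequency of a use is (number of participants giving that use) /
(total number of participants in the scoring sample) — the denominator
includes participants with no responses for that item, so e.g. a use given by
10 of 75 participants has relative frequency 0.13. Uses are compared within
an item only; an identical token for "bucket" and "comb" counts as two
distinct uses. Duplicate tokens within one participant-item are counted once.

Overcoming Knowledge Constraints (OKC): drawings of an alien animal are coded
for three example-primed elements (four limbs, two antennae, tail); the score
is reversed, 3 minus the number of elements present, so higher = less
constrained by the examples.

Leisure engagement: per activity domain, the sum over endorsed activities of
a days-per-week weight for the reported frequency category (less than once =
0.5, 1-2 days = 1.5, 3-4 days = 3.5, 5-6 days = 5.5, every day = 7). Only
the creative-hobbies domain enters the analysis table.

A "valid response" is any non-empty token after canonicalization; no semantic
judgement of whether a use is genuinely non-normal is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variables import AUT_ITEMS

__all__ = [
    "LEISURE_WEIGHTS",
    "LEISURE_DOMAINS",
    "AUTResponseSet",
    "UseFrequencyTable",
    "canonicalize_use",
    "build_frequency_table",
    "score_fluency",
    "score_overall_originality",
    "score_peak_originality",
    "score_okc",
    "score_leisure",
    "score_aut",
]

#: Days-per-week weight for each leisure frequency category.
LEISURE_WEIGHTS: dict[str, float] = {
    "less than once": 0.5,
    "1-2 days": 1.5,
    "3-4 days": 3.5,
    "5-6 days": 5.5,
    "every day": 7.0,
}

LEISURE_DOMAINS: tuple[str, ...] = ("creative", "physical", "socializing", "sedentary")

OKC_ELEMENTS: tuple[str, ...] = ("four_limbs", "two_antennae", "tail")

_WS = re.compile(r"\s+")


def canonicalize_use(raw_text: str, synonyms: dict[str, str] | None = None) -> str:
    """Normalize a free-text use to a canonical token.

    Lowercases, trims, collapses internal whitespace, then applies an optional
    synonym map. Idempotent. Blank input is rejected (invalid response).
    """
    if raw_text is None or not str(raw_text).strip():
        raise ValueError("empty response is not a valid use")
    token = _WS.sub(" ", str(raw_text).strip().lower())
    if synonyms:
        token = synonyms.get(token, token)
    return token


@dataclass
class AUTResponseSet:
    """Per-participant, per-item lists of canonical use tokens.

    ``participants`` is the full scoring sample (it may include participants
    with no responses; they define the relative-frequency denominator).
    """

    entries: dict[tuple[str, str], list[str]]
    participants: list[str]
    items: tuple[str, ...] = AUT_ITEMS

    def __post_init__(self) -> None:
        for (pid, item), tokens in self.entries.items():
            if item not in self.items:
                raise ValueError(f"unknown AUT item {item!r} for participant {pid!r}")
            if len(set(tokens)) != len(tokens):
                raise ValueError(f"duplicate canonical tokens for ({pid!r}, {item!r})")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        participants: list[str] | None = None,
        synonyms: dict[str, str] | None = None,
        items: tuple[str, ...] = AUT_ITEMS,
    ) -> "AUTResponseSet":
        """Build from a long table (participant_id, item, response_text).

        Blank responses are dropped as invalid; duplicate canonical tokens
        within a participant-item are counted once.
        """
        entries: dict[tuple[str, str], list[str]] = {}
        for row in frame.itertuples(index=False):
            pid, item, text = str(row.participant_id), str(row.item), row.response_text
            if text is None or not str(text).strip():
                continue
            token = canonicalize_use(text, synonyms)
            bucket = entries.setdefault((pid, item), [])
            if token not in bucket:
                bucket.append(token)
        if participants is None:
            participants = sorted({pid for pid, _ in entries})
        return cls(entries=entries, participants=list(map(str, participants)), items=items)

    def tokens(self, participant: str, item: str) -> list[str]:
        return self.entries.get((str(participant), item), [])


@dataclass
class UseFrequencyTable:
    """Per-item relative frequency of each use across the scoring sample.

    frequency = (count of participants giving that use) / n_total, where
    n_total is the full scoring-sample size. Counts are retained so the
    10%-or-less peak-originality threshold is exact.
    """

    counts: dict[str, dict[str, int]]
    n_total: int
    frequencies: dict[str, dict[str, float]] = field(init=False)

    def __post_init__(self) -> None:
        self.frequencies = {
            item: {use: c / self.n_total for use, c in uses.items()}
            for item, uses in self.counts.items()
        }

    def frequency(self, item: str, use: str) -> float:
        return self.frequencies[item][use]


def build_frequency_table(responses: AUTResponseSet) -> UseFrequencyTable:
    """Count, per item, how many participants gave each use."""
    if not responses.participants:
        raise ValueError("cannot build a frequency table from an empty sample")
    counts: dict[str, dict[str, int]] = {item: {} for item in responses.items}
    for (pid, item), tokens in responses.entries.items():
        for token in tokens:
            counts[item][token] = counts[item].get(token, 0) + 1
    return UseFrequencyTable(counts=counts, n_total=len(responses.participants))


def score_fluency(responses: AUTResponseSet, participant: str) -> float:
    """Mean valid-response count over the three items (zero-response items count 0)."""
    counts = [len(responses.tokens(participant, item)) for item in responses.items]
    return float(np.mean(counts))


def score_overall_originality(
    responses: AUTResponseSet, freq: UseFrequencyTable, participant: str
) -> float:
    """1 minus the mean relative frequency of the participant's uses.

    Per item with at least one response: 1 - (sum of its uses' relative
    frequencies / response count); the score is the mean over items that have
    responses. Missing (NaN) if the participant gave no responses at all.
    """
    per_item = []
    for item in responses.items:
        tokens = responses.tokens(participant, item)
        if not tokens:
            continue
        mean_rf = sum(freq.frequency(item, t) for t in tokens) / len(tokens)
        per_item.append(1.0 - mean_rf)
    if not per_item:
        return float("nan")
    return float(np.mean(per_item))


def score_peak_originality(
    responses: AUTResponseSet,
    freq: UseFrequencyTable,
    participant: str,
    threshold: float = 0.10,
) -> int:
    """Count of the participant's uses given by ``threshold`` (10%) or less of the sample.

    Inclusive threshold, compared exactly on participant counts.
    """
    n_total = freq.n_total
    count = 0
    for item in responses.items:
        for token in responses.tokens(participant, item):
            if freq.counts[item][token] <= threshold * n_total + 1e-12:
                count += 1
    return count


def score_okc(element_flags) -> int:
    """Reverse-scored element count: 3 minus the number of primed elements present."""
    flags = list(element_flags)
    if len(flags) != 3 or any(f not in (0, 1) for f in flags):
        raise ValueError("OKC flags must be three 0/1 indicators")
    return 3 - sum(flags)


def score_leisure(activity_table: pd.DataFrame) -> pd.DataFrame:
    """Per-domain engagement: sum of category weights over endorsed activities.

    ``activity_table`` is long-format with columns (participant_id, domain,
    activity, frequency); unknown frequency categories raise naming the row.
    Participants with no endorsed activities in a domain score 0.
    """
    required = {"participant_id", "domain", "frequency"}
    if not required.issubset(activity_table.columns):
        raise ValueError(f"leisure table needs columns {sorted(required)}")
    pids = activity_table["participant_id"].astype(str)
    out = pd.DataFrame(
        0.0,
        index=pd.Index(sorted(pids.unique()), name="participant_id"),
        columns=list(LEISURE_DOMAINS),
    )
    for i, row in enumerate(activity_table.itertuples(index=False)):
        if row.frequency not in LEISURE_WEIGHTS:
            raise ValueError(
                f"leisure row {i} (participant {row.participant_id!r}, "
                f"activity {getattr(row, 'activity', '?')!r}): unknown frequency "
                f"category {row.frequency!r}"
            )
        if row.domain not in LEISURE_DOMAINS:
            raise ValueError(f"leisure row {i}: unknown domain {row.domain!r}")
        out.loc[str(row.participant_id), row.domain] += LEISURE_WEIGHTS[row.frequency]
    return out


def score_aut(responses: AUTResponseSet, peak_threshold: float = 0.10) -> pd.DataFrame:
    """All three AUT indices for every participant in the scoring sample."""
    freq = build_frequency_table(responses)
    rows = {}
    for pid in responses.participants:
        rows[pid] = {
            "aut_fluency": score_fluency(responses, pid),
            "aut_overall_originality": score_overall_originality(responses, freq, pid),
            "aut_peak_originality": score_peak_originality(responses, freq, pid, peak_threshold),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "participant_id"
    return out
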