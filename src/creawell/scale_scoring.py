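"""Scoring of the self-report instruments into analysis variables.

Four instruments are scored:

* **SWLS-C** — 5-item children's Satisfaction With Life scale, 1-5 responses,
  scored as the item mean (a single 1-5 life-satisfaction score).
* **SPANE** — 12-item Scale of Positive And Negative Experience, 1-5
  responses, scored as two sums (positive affect, negative affect), each over
  a declared 6-item partition, range 6-30.
* **MHC-SF** — 14-item Mental Health Continuum Short Form over six ordered
  frequency categories coded 0 ("never") to 5 ("every day"), scored as the
  item mean (0-5).
* **SPQ-BRU** — 32-item Brief Revised Updated Schizotypal Personality
  Questionnaire, 1-5 responses summed into nine subscales of 3-4 items each,
  three higher-order factors (cognitive-perceptual, interpersonal,
  disorganized) that are sums of their constituent subscales, and a total
  score over all 32 items (so the total also spans the social-anxiety
  subscale, which belongs to none of the three reported factors).

Missing data policy: no proration — any missing item voids that instrument's
score(s) for the participant, which produces instrument-level (not item-level)
missingness downstream.

The exact SPQ-BRU item->subscale assignment and the SPANE item partition are
configuration inputs; the defaults below follow the instruments' published
structure with sequential item numbering and are not verified against any
particular administration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SPANE_PARTITION",
    "DEFAULT_SPQ_SUBSCALES",
    "SPQ_FACTORS",
    "ReliabilityResult",
    "score_swlsc",
    "score_spane",
    "score_mhcsf",
    "score_spq",
    "score_all_scales",
    "cronbach_alpha",
    "reverse_code",
]

def _item_cols(n: int) -> list[str]:
    return [f"item{i:02d}" for i in range(1, n + 1)]

#: SPANE positive/negative item partition (published ordering).
DEFAULT_SPANE_PARTITION: dict[str, tuple[str, ...]] = {
    "positive": tuple(f"item{i:02d}" for i in (1, 3, 5, 7, 10, 12)),
    "negative": tuple(f"item{i:02d}" for i in (2, 4, 6, 8, 9, 11)),
}

#: SPQ-BRU nine subscales, 3-4 items each, 32 items total, sequential items.
_SPQ_SIZES = {
    "ideas_of_reference": 4,
    "suspiciousness": 3,
    "magical_thinking": 4,
    "unusual_perceptions": 4,
    "social_anxiety": 4,
    "no_close_friends": 3,
    "constricted_affect": 3,
    "eccentric_behavior": 4,
    "odd_speech": 3,
}

def _build_spq_subscales() -> dict[str, tuple[str, ...]]:
    out, start = {}, 1
    for name, size in _SPQ_SIZES.items():
        out[name] = tuple(f"item{i:02d}" for i in range(start, start + size))
        start += size
    return out

DEFAULT_SPQ_SUBSCALES: dict[str, tuple[str, ...]] = _build_spq_subscales()

#: Higher-order factor -> constituent subscales.
SPQ_FACTORS: dict[str, tuple[str, ...]] = {
    "spq_cognitive_perceptual": (
        "ideas_of_reference",
        "suspiciousness",
        "magical_thinking",
        "unusual_perceptions",
    ),
    "spq_interpersonal": ("no_close_friends", "constricted_affect"),
    "spq_disorganized": ("eccentric_behavior", "odd_speech"),
}


@dataclass(frozen=True)
class ReliabilityResult:
    """Cronbach's alpha with the item and case counts it was computed on."""

    alpha: float
    k_items: int
    n_cases: int
    zero_variance: bool = False


def _validate_items(matrix: pd.DataFrame, k: int, lo: int, hi: int, name: str) -> pd.DataFrame:
    cols = _item_cols(k)
    missing_cols = [c for c in cols if c not in matrix.columns]
    if missing_cols:
        raise ValueError(f"{name}: missing item columns {missing_cols}")
    data = matrix[cols].astype(float)
    vals = data.to_numpy()
    bad = vals[~np.isnan(vals)]
    if bad.size and ((bad < lo) | (bad > hi) | (bad != np.round(bad))).any():
        raise ValueError(f"{name}: item responses must be integers in {lo}-{hi}")
    return data


def score_swlsc(matrix: pd.DataFrame) -> pd.Series:
    """Life satisfaction: mean of the five 1-5 items; missing if any item is."""
    data = _validate_items(matrix, 5, 1, 5, "SWLS-C")
    score = data.mean(axis=1)
    score[data.isna().any(axis=1)] = np.nan
    return score.rename("life_satisfaction")


def score_spane(
    matrix: pd.DataFrame,
    partition: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Positive/negative affect sums (6-30 each) over a declared 6/6 partition."""
    partition = partition or DEFAULT_SPANE_PARTITION
    pos, neg = tuple(partition["positive"]), tuple(partition["negative"])
    if len(pos) != 6 or len(neg) != 6 or set(pos) & set(neg):
        raise ValueError("SPANE partition must declare 6 disjoint positive and 6 negative items")
    data = _validate_items(matrix, 12, 1, 5, "SPANE")
    any_missing = data.isna().any(axis=1)
    out = pd.DataFrame(
        {
            "positive_affect": data[list(pos)].sum(axis=1),
            "negative_affect": data[list(neg)].sum(axis=1),
        }
    )
    out[any_missing] = np.nan
    return out


def score_mhcsf(matrix: pd.DataFrame) -> pd.Series:
    """Mental health: mean of the 14 items coded 0 (never) .. 5 (every day)."""
    data = _validate_items(matrix, 14, 0, 5, "MHC-SF")
    score = data.mean(axis=1)
    score[data.isna().any(axis=1)] = np.nan
    return score.rename("mental_health")


def score_spq(
    matrix: pd.DataFrame,
    subscale_map: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """SPQ-BRU subscale sums, the three factor sums, and the 32-item total.

    ``subscale_map`` must cover all 32 items exactly once across the nine
    subscales named in :data:`DEFAULT_SPQ_SUBSCALES`.
    """
    subscale_map = subscale_map or DEFAULT_SPQ_SUBSCALES
    if set(subscale_map) != set(_SPQ_SIZES):
        raise ValueError("SPQ subscale map must name exactly the nine subscales")
    all_items = [it for items in subscale_map.values() for it in items]
    if len(all_items) != 32 or len(set(all_items)) != 32:
        raise ValueError("SPQ subscale map must cover all 32 items exactly once")
    for name, items in subscale_map.items():
        if not 3 <= len(items) <= 4:
            raise ValueError(f"SPQ subscale {name!r} must have 3-4 items")
    data = _validate_items(matrix, 32, 1, 5, "SPQ-BRU")
    any_missing = data.isna().any(axis=1)

    out = pd.DataFrame(index=matrix.index)
    for name, items in subscale_map.items():
        out[name] = data[list(items)].sum(axis=1)
    for factor, subs in SPQ_FACTORS.items():
        out[factor] = out[list(subs)].sum(axis=1)
    out["spq_total"] = data.sum(axis=1)
    out[any_missing] = np.nan
    return out


def score_all_scales(
    swlsc: pd.DataFrame,
    spane: pd.DataFrame,
    mhcsf: pd.DataFrame,
    spq: pd.DataFrame,
    spane_partition: dict[str, tuple[str, ...]] | None = None,
    spq_subscales: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Score all four instruments into one table of analysis variables.

    Inputs are wide item tables indexed by participant id; participants absent
    from an instrument's table get missing scores for that instrument.
    """
    index = sorted(set(swlsc.index) | set(spane.index) | set(mhcsf.index) | set(spq.index))
    out = pd.DataFrame(index=pd.Index(index, name=swlsc.index.name or "participant_id"))
    out["life_satisfaction"] = score_swlsc(swlsc)
    out = out.join(score_spane(spane, spane_partition))
    out["mental_health"] = score_mhcsf(mhcsf)
    spq_scores = score_spq(spq, spq_subscales)
    out = out.join(spq_scores[list(SPQ_FACTORS) + ["spq_total"]])
    return out


def cronbach_alpha(item_matrix: pd.DataFrame | np.ndarray) -> ReliabilityResult:
    """Internal-consistency reliability, alpha = k/(k-1) * (1 - sum(var_i)/var_total).

    Computed on complete cases with sample (n-1) variances. Requires at least
    two items and three complete cases. When the total-score variance is zero
    alpha is undefined and returned as NaN with ``zero_variance=True``.
    """
    data = pd.DataFrame(item_matrix).astype(float).dropna(axis=0, how="any")
    k = data.shape[1]
    n = data.shape[0]
    if k < 2:
        raise ValueError("cronbach_alpha requires at least 2 items")
    if n < 3:
        raise ValueError("cronbach_alpha requires at least 3 complete cases")
    item_vars = data.var(axis=0, ddof=1)
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return ReliabilityResult(alpha=float("nan"), k_items=k, n_cases=n, zero_variance=True)
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    return ReliabilityResult(alpha=float(alpha), k_items=k, n_cases=n)


def reverse_code(matrix: pd.DataFrame, items: list[str], lo: int, hi: int) -> pd.DataFrame:
    """Reverse-code the named items on a lo..hi response scale.

    ``x -> lo + hi - x``; applying the hook twice is the identity. No items
    are reverse-coded by default in any instrument here; the hook exists for
    reuse with instruments that need it.
    """
    out = matrix.copy()
    out[items] = (lo + hi) - out[items]
    return out
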