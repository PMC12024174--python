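"""Canonical analysis-variable ordering shared across the pipeline.

The 13 analysis variables cover three creativity-potential indices from the
Alternate Uses Task (AUT), the Overcoming Knowledge Constraints drawing score,
four wellbeing scores, weekly engagement in creative hobbies, and the four
schizotypy scores from the SPQ-BRU (three higher-order factors plus the total).
All tables, correlation matrices and reports use this order.
"""

from __future__ import annotations

ANALYSIS_VARIABLES: tuple[str, ...] = (
    "aut_fluency",
    "aut_overall_originality",
    "aut_peak_originality",
    "okc",
    "life_satisfaction",
    "positive_affect",
    "negative_affect",
    "mental_health",
    "creative_hobbies",
    "spq_cognitive_perceptual",
    "spq_interpersonal",
    "spq_disorganized",
    "spq_total",
)

#: Human-readable labels for reports.
VARIABLE_LABELS: dict[str, str] = {
    "aut_fluency": "AUT fluency",
    "aut_overall_originality": "AUT overall originality",
    "aut_peak_originality": "AUT peak originality",
    "okc": "OKC raw score",
    "life_satisfaction": "Life satisfaction",
    "positive_affect": "Positive affect",
    "negative_affect": "Negative affect",
    "mental_health": "Mental health",
    "creative_hobbies": "Creative hobbies",
    "spq_cognitive_perceptual": "SPQ cognitive perceptual",
    "spq_interpersonal": "SPQ interpersonal",
    "spq_disorganized": "SPQ disorganized",
    "spq_total": "SPQ total",
}

AUT_ITEMS: tuple[str, ...] = ("bucket", "comb", "belt")

AGE_COLUMN = "age"
ID_COLUMN = "participant_id"
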