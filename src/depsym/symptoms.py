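"""The five retained PHQ-8 symptom categories and shared label conventions."""

# PHQ-8 items retained for dual-source analysis.  Appetite, concentration
# and psychomotor items are not represented: their social-media signal is
# either too sparse or too ambiguous to detect lexically.
SYMPTOMS: tuple[str, ...] = (
    "diminished_interest",
    "depressed_mood",
    "insomnia_hypersomnia",
    "fatigue_energy_loss",
    "worthlessness_guilt",
)

#: survey CSV column per symptom item
ITEM_COLUMNS: dict[str, str] = {
    "diminished_interest": "item_interest",
    "depressed_mood": "item_mood",
    "insomnia_hypersomnia": "item_sleep",
    "fatigue_energy_loss": "item_fatigue",
    "worthlessness_guilt": "item_worth",
}

SEX_LEVELS: tuple[str, ...] = ("male", "female")

#: age-group labels by source; surveys sample from 15, tweets are attributed
#: from 10 upward.  Harmonized to "<18" where the sources must align.
SURVEY_AGE_GROUPS: tuple[str, ...] = ("15-17", "18-24", "25-34", "35-49", "50+")
TWITTER_AGE_GROUPS: tuple[str, ...] = ("10-17", "18-24", "25-34", "35-49", "50+")
HARMONIZED_AGE_GROUPS: tuple[str, ...] = ("<18", "18-24", "25-34", "35-49", "50+")

PERIODS: tuple[str, ...] = ("before", "during", "after")


def harmonize_age_group(label: str) -> str:
    """Map source-specific youngest age labels onto the shared "<18" level."""
    if label in ("10-17", "15-17"):
        return "<18"
    if label not in HARMONIZED_AGE_GROUPS:
        raise ValueError(f"unknown age group label: {label!r}")
    return label
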