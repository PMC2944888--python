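"""Packaged list of 10-letter high-frequency English words.

Synthetic stand-in list, hand-compiled, used as the stimulus pool for the
hard text-entry task (the word is shown once and must be typed from
memory) and, scrambled, for the easy version.  Every entry has exactly ten
letters and no letter occurring more than five times, so a
no-adjacent-repeat scramble always exists.
"""

WORDS_10 = (
    "university",
    "background",
    "basketball",
    "generation",
    "television",
    "restaurant",
    "technology",
    "management",
    "population",
    "experience",
    "government",
    "department",
    "individual",
    "everything",
    "understand",
    "commercial",
    "production",
    "collection",
    "particular",
    "discussion",
    "foundation",
    "washington",
    "importance",
    "friendship",
    "leadership",
    "assessment",
    "difficulty",
    "conclusion",
    "laboratory",
    "literature",
    "psychology",
    "retirement",
    "motivation",
    "newspapers",
    "impression",
    "journalist",
    "vegetables",
    "excitement",
    "instrument",
    "mechanical",
)
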