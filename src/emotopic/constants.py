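"""Fixed category systems used throughout the package."""

#: Plutchik's eight basic emotions, alphabetical.
EMOTIONS = (
    "anger",
    "anticipation",
    "disgust",
    "fear",
    "joy",
    "sadness",
    "surprise",
    "trust",
)

#: The two sentiment polarities carried alongside the emotions.
SENTIMENTS = ("negative", "positive")

#: The full 10-category system of an EmoLex-style word-emotion lexicon.
CATEGORIES = EMOTIONS + SENTIMENTS

#: Recognised gender labels for user records.
GENDERS = ("woman", "man", "unknown")
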