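"""Emotion item vocabulary for the high-frequency emotion/intensity protocol."""

from __future__ import annotations

POSITIVE_EMOTIONS = ("happy", "interest")
NEGATIVE_EMOTIONS = ("anxious", "angry", "shame", "disgust", "sad", "guilt", "envy/jealousy")
NO_EMOTION = "no emotion"
UNNAMEABLE = "emotion but cannot name it"

PLEASANT = "pleasant"
UNPLEASANT = "unpleasant"

ALL_ITEMS = POSITIVE_EMOTIONS + NEGATIVE_EMOTIONS + (UNNAMEABLE, NO_EMOTION)

_ALIASES = {
    "no_emotion": NO_EMOTION,
    "cannot name it": UNNAMEABLE,
    "cannot_name_it": UNNAMEABLE,
}


def canonical_label(label: str) -> str:
    """Normalize an emotion item label (case/underscore tolerant)."""
    key = str(label).strip().lower()
    key = _ALIASES.get(key, key)
    key = _ALIASES.get(key.replace("_", " "), key.replace("_", " "))
    return key
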