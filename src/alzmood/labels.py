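"""Closed vocabularies shared across the package.

Pose observations use single letters: C (walking), S (sitting), P (standing).
Mood labels form a closed six-way enumeration; ``Mood.NONE`` stands for the
"nothing" / "no observation" category.
"""

from __future__ import annotations

from enum import Enum


class Mood(str, Enum):
    """The five mood states inferred for Alzheimer's patients, plus none."""

    WANDERING = "wandering"
    NERVOUS = "nervous"
    DEPRESSED = "depressed"
    DISORIENTED = "disoriented"
    BORED = "bored"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Valid pose letters, in the canonical order walking, sitting, standing.
POSE_LETTERS: tuple[str, ...] = ("C", "S", "P")

#: Pose letter -> activity pattern (the Pattern-class subclasses).
LETTER_TO_PATTERN: dict[str, str] = {"C": "walking", "S": "sitting", "P": "standing"}

#: Activity pattern -> pose letter.
PATTERN_TO_LETTER: dict[str, str] = {v: k for k, v in LETTER_TO_PATTERN.items()}

#: Fixed tie-break priority for classification: earlier wins ties.
MOOD_PRIORITY: tuple[Mood, ...] = (
    Mood.WANDERING,
    Mood.NERVOUS,
    Mood.DEPRESSED,
    Mood.DISORIENTED,
    Mood.BORED,
    Mood.NONE,
)


def mood_rank(mood: Mood) -> int:
    """Position of ``mood`` in the fixed priority order (0 = highest)."""
    return MOOD_PRIORITY.index(mood)


def check_pose_letter(letter: str) -> str:
    """Validate a pose letter, returning it; raise ValueError otherwise."""
    if letter not in POSE_LETTERS:
        raise ValueError(f"invalid pose letter {letter!r}; expected one of {POSE_LETTERS}")
    return letter
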