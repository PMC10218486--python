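"""Pose-pair and pose-window classification into mood labels.

The core device is a nine-entry code table over ordered pairs of pose
letters (C = walking, S = sitting, P = standing):

    CC -> wandering    CS -> nervous      SC -> nervous
    SS -> depressed    CP -> disoriented  PC -> disoriented
    PS -> bored        SP -> bored        PP -> none

Clean streams are classified by sliding pair lookup.  Noisy windows are
matched against canonical mood templates under the restricted (adjacent
transposition) Damerau-Levenshtein distance; the nearest template's mood
wins, with ties broken by a fixed priority order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TYPE_CHECKING

from alzmood.labels import Mood, MOOD_PRIORITY, POSE_LETTERS, check_pose_letter, mood_rank

if TYPE_CHECKING:  # pragma: no cover
    from alzmood.ingest import PoseStream

_DEFAULT_PAIRS: dict[tuple[str, str], Mood] = {
    ("C", "C"): Mood.WANDERING,
    ("C", "S"): Mood.NERVOUS,
    ("S", "C"): Mood.NERVOUS,
    ("S", "S"): Mood.DEPRESSED,
    ("C", "P"): Mood.DISORIENTED,
    ("P", "C"): Mood.DISORIENTED,
    ("P", "S"): Mood.BORED,
    ("S", "P"): Mood.BORED,
    ("P", "P"): Mood.NONE,
}


@dataclass(frozen=True)
class PairCodeTable:
    """Total mapping from the 9 ordered pose-letter pairs to mood labels."""

    mapping: dict[tuple[str, str], Mood] = field(
        default_factory=lambda: dict(_DEFAULT_PAIRS)
    )

    def __post_init__(self) -> None:
        expected = {(a, b) for a in POSE_LETTERS for b in POSE_LETTERS}
        if set(self.mapping) != expected:
            missing = expected - set(self.mapping)
            extra = set(self.mapping) - expected
            raise ValueError(
                f"pair table must be total over the 9 ordered pairs; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    def __getitem__(self, pair: tuple[str, str]) -> Mood:
        return self.mapping[pair]

    @classmethod
    def from_config(cls, entries: dict[str, str]) -> "PairCodeTable":
        """Build from JSON-style config, e.g. ``{"CC": "wandering", ...}``."""
        return cls({(k[0], k[1]): Mood(v) for k, v in entries.items()})


DEFAULT_PAIR_TABLE = PairCodeTable()


def classify_pair(a: str, b: str, table: PairCodeTable = DEFAULT_PAIR_TABLE) -> Mood:
    """Exact code-table lookup for one ordered pose pair."""
    return table[(check_pose_letter(a), check_pose_letter(b))]


def damerau_levenshtein(x: str, y: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance.

    Unit-cost insertions, deletions, substitutions, and adjacent
    transpositions; each substring may take part in at most one
    transposition.  Symmetric, zero iff the strings are equal.
    """
    n, m = len(x), len(y)
    if n == 0:
        return m
    if m == 0:
        return n
    prev2: list[int] = []
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cost = 0 if x[i - 1] == y[j - 1] else 1
            best = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and x[i - 1] == y[j - 2] and x[i - 2] == y[j - 1]:
                best = min(best, prev2[j - 2] + 1)
            cur[j] = best
        prev2, prev = prev, cur
    return prev[m]


def classify_stream(
    stream: "PoseStream",
    table: PairCodeTable = DEFAULT_PAIR_TABLE,
    overlapping: bool = True,
) -> list[tuple[int, Mood]]:
    """Label every adjacent pose pair of a stream.

    With ``overlapping`` (default) the window slides one event at a time,
    giving len(events) - 1 labels, each stamped with the time of the pair's
    second event.  ``overlapping=False`` uses disjoint pairs instead.
    """
    events = stream.events
    if len(events) < 2:
        raise ValueError(
            f"stream {stream.patient_id!r} has {len(events)} event(s); "
            "need at least 2 to classify"
        )
    step = 1 if overlapping else 2
    out: list[tuple[int, Mood]] = []
    for i in range(0, len(events) - 1, step):
        a, b = events[i], events[i + 1]
        out.append((b.t, classify_pair(a.pose, b.pose, table)))
    return out


@dataclass(frozen=True)
class CanonicalPattern:
    """A mood's canonical pose-letter template for window matching."""

    mood: Mood
    template: str

    def __post_init__(self) -> None:
        if not self.template:
            raise ValueError("template must be nonempty")
        for ch in self.template:
            check_pose_letter(ch)

    def tiled(self, length: int) -> str:
        """Template repeated/truncated to ``length`` characters."""
        reps = -(-length // len(self.template))
        return (self.template * reps)[:length]


def default_templates(table: PairCodeTable = DEFAULT_PAIR_TABLE) -> list[CanonicalPattern]:
    """Length-4 canonical templates, one per mood, derived from the pair table.

    Each template is a pair code repeated to length 4 (wandering "CCCC",
    nervous "CSCS", ...), so every adjacent pair inside a template maps back
    to the template's own mood.
    """
    seeds = {
        Mood.WANDERING: "CC",
        Mood.NERVOUS: "CS",
        Mood.DEPRESSED: "SS",
        Mood.DISORIENTED: "CP",
        Mood.BORED: "SP",
        Mood.NONE: "PP",
    }
    patterns = []
    for mood in MOOD_PRIORITY:
        tpl = (seeds[mood] * 2)[:4]
        for i in range(3):
            assert classify_pair(tpl[i], tpl[i + 1], table) == mood
        patterns.append(CanonicalPattern(mood, tpl))
    return patterns


DEFAULT_TEMPLATES: list[CanonicalPattern] = default_templates()


def classify_window(
    window: str,
    patterns: Sequence[CanonicalPattern] = DEFAULT_TEMPLATES,
    return_all: bool = False,
):
    """Nearest-canonical-template matching for a noisy pose window.

    Each template is tiled/truncated to the window length, distances are
    computed under restricted Damerau-Levenshtein, and the minimum-distance
    mood is returned as ``(mood, distance)``.  Ties break by the fixed
    priority wandering > nervous > depressed > disoriented > bored > none.
    With ``return_all`` the per-mood distance dict is returned as a third
    element so ties are visible.
    """
    if not window:
        raise ValueError("window must be nonempty")
    if not patterns:
        raise ValueError("patterns must be nonempty")
    for ch in window:
        check_pose_letter(ch)
    distances: dict[Mood, int] = {}
    for pat in patterns:
        d = damerau_levenshtein(window, pat.tiled(len(window)))
        if pat.mood not in distances or d < distances[pat.mood]:
            distances[pat.mood] = d
    best = min(distances.items(), key=lambda kv: (kv[1], mood_rank(kv[0])))
    if return_all:
        return best[0], best[1], distances
    return best
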