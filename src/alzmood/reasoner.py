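"""Forward-chaining inference of patient-level mood states.

A StateRule links a mood to the activity patterns that evidence it and a
minimum number of repetitions.  The default rule set encodes the domain
axioms: bored, disoriented and nervous are evidenced by sitting/standing,
depressed by sitting, and wandering by walking sustained over at least
four consecutive observations.  A rule fires when a patient's stream
contains a maximal run of consecutive qualifying events at least as long
as the rule's threshold.

Because the pair-code classifier and the state rules come from two
different sources in the underlying model, ``audit_rule_consistency``
compares the pattern sets both assign to each mood and flags moods on
which they disagree rather than silently resolving the conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from alzmood.classifier import PairCodeTable, DEFAULT_PAIR_TABLE
from alzmood.ingest import PoseCodeMap, DEFAULT_CODE_MAP, PoseEvent, PoseStream
from alzmood.labels import LETTER_TO_PATTERN, Mood, PATTERN_TO_LETTER, mood_rank
from alzmood.ontology import OntologyModel, OntologyError, is_subclass_of

_PATTERNS = frozenset(LETTER_TO_PATTERN.values())


@dataclass(frozen=True)
class StateRule:
    """Allowed activity patterns and repetition threshold for one mood."""

    mood: Mood
    allowed_patterns: frozenset[str]
    min_repetitions: int = 1

    def __post_init__(self) -> None:
        if not self.allowed_patterns:
            raise ValueError(f"rule for {self.mood}: allowed_patterns is empty")
        unknown = set(self.allowed_patterns) - _PATTERNS
        if unknown:
            raise ValueError(f"rule for {self.mood}: unknown patterns {sorted(unknown)}")
        if self.min_repetitions < 1:
            raise ValueError(f"rule for {self.mood}: min_repetitions must be >= 1")


DEFAULT_RULES: list[StateRule] = [
    StateRule(Mood.BORED, frozenset({"sitting", "standing"}), 1),
    StateRule(Mood.DISORIENTED, frozenset({"sitting", "standing"}), 1),
    StateRule(Mood.DEPRESSED, frozenset({"sitting"}), 1),
    StateRule(Mood.WANDERING, frozenset({"walking"}), 4),
    StateRule(Mood.NERVOUS, frozenset({"sitting", "standing"}), 1),
]


@dataclass
class Firing:
    """One rule firing: the supporting run of consecutive events."""

    rule: StateRule
    start_index: int
    run_length: int


@dataclass
class InferenceResult:
    """All mood states asserted for one patient, with supporting firings."""

    patient_id: str
    asserted_states: set[Mood] = field(default_factory=set)
    firings: list[Firing] = field(default_factory=list)

    @property
    def primary_state(self) -> Mood | None:
        """Highest-priority asserted state, or None when nothing fired."""
        if not self.asserted_states:
            return None
        return min(self.asserted_states, key=mood_rank)


def _maximal_runs(events: Sequence[PoseEvent], allowed: frozenset[str]):
    """Yield (start_index, length) of maximal runs of qualifying events."""
    start = None
    for i, ev in enumerate(events):
        if ev.pattern in allowed:
            if start is None:
                start = i
        elif start is not None:
            yield start, i - start
            start = None
    if start is not None:
        yield start, len(events) - start


def apply_state_rules(
    stream: PoseStream,
    rules: Sequence[StateRule] = DEFAULT_RULES,
    consecutive: bool = True,
) -> InferenceResult:
    """Fire every rule supported by the stream.

    With ``consecutive`` (default) a rule fires iff some maximal run of
    consecutive qualifying events reaches its threshold; with
    ``consecutive=False`` the total count of qualifying events is used
    instead.  An empty stream asserts nothing.
    """
    result = InferenceResult(patient_id=stream.patient_id)
    for rule in rules:
        if consecutive:
            for start, length in _maximal_runs(stream.events, rule.allowed_patterns):
                if length >= rule.min_repetitions:
                    result.asserted_states.add(rule.mood)
                    result.firings.append(Firing(rule, start, length))
        else:
            count = sum(1 for ev in stream.events if ev.pattern in rule.allowed_patterns)
            if count >= rule.min_repetitions:
                result.asserted_states.add(rule.mood)
                result.firings.append(Firing(rule, 0, count))
    return result


def min_trigger_run(mood: Mood, rules: Sequence[StateRule] = DEFAULT_RULES, limit: int = 100) -> int:
    """Smallest run of qualifying events that asserts ``mood``, found by probing.

    Builds synthetic streams of k = 1, 2, 3, ... qualifying events and calls
    apply_state_rules until the mood is asserted; this measures the engine's
    behaviour rather than reading the threshold off the rule.
    """
    matching = [r for r in rules if r.mood == mood]
    if not matching:
        raise ValueError(f"no rule for mood {mood}")
    pattern = sorted(matching[0].allowed_patterns)[0]
    letter = PATTERN_TO_LETTER[pattern]
    for k in range(1, limit + 1):
        stream = PoseStream(
            patient_id="probe",
            events=[PoseEvent(t=i, pose=letter, patient_id="probe") for i in range(k)],
        )
        if mood in apply_state_rules(stream, rules).asserted_states:
            return k
    raise ValueError(f"mood {mood} not asserted within {limit} events")


def instance_check(model: OntologyModel, individual: str, cls: str) -> bool:
    """True iff the individual's asserted class is ``cls`` or a descendant of it."""
    if cls not in model.classes:
        raise OntologyError(f"unknown class {cls!r}")
    asserted = model.individual_class(individual)
    return is_subclass_of(model, asserted, cls)


@dataclass
class ConflictEntry:
    """Per-mood comparison between the pair-code table and the state rules."""

    mood: Mood
    pair_table_patterns: frozenset[str]
    rule_patterns: frozenset[str]

    @property
    def agree(self) -> bool:
        return self.pair_table_patterns == self.rule_patterns


@dataclass
class ConflictReport:
    entries: list[ConflictEntry]

    def disagreements(self) -> list[ConflictEntry]:
        return [e for e in self.entries if not e.agree]

    def to_text(self) -> str:
        lines = ["mood         pair-table patterns        rule patterns              agree"]
        for e in sorted(self.entries, key=lambda e: mood_rank(e.mood)):
            lines.append(
                f"{e.mood.value:<12} {','.join(sorted(e.pair_table_patterns)) or '-':<26} "
                f"{','.join(sorted(e.rule_patterns)) or '-':<26} {e.agree}"
            )
        return "\n".join(lines)


def audit_rule_consistency(
    table: PairCodeTable = DEFAULT_PAIR_TABLE,
    rules: Sequence[StateRule] = DEFAULT_RULES,
    code_map: PoseCodeMap = DEFAULT_CODE_MAP,
) -> ConflictReport:
    """Compare each mood's pair-code patterns with its rule's patterns.

    For every mood in either source, the set of activity patterns occurring
    in its pair codes (letters decoded to patterns) is compared with the
    rule's allowed_patterns; moods present in only one source never agree.
    ``code_map`` fixes which letters are in play (its codomain), guarding
    against partial remappings.
    """
    letters_in_play = set(code_map.mapping.values())
    pair_patterns: dict[Mood, set[str]] = {}
    for (a, b), mood in table.mapping.items():
        if a in letters_in_play and b in letters_in_play:
            pair_patterns.setdefault(mood, set()).update(
                (LETTER_TO_PATTERN[a], LETTER_TO_PATTERN[b])
            )
    rule_patterns: dict[Mood, set[str]] = {}
    for rule in rules:
        rule_patterns.setdefault(rule.mood, set()).update(rule.allowed_patterns)
    entries = [
        ConflictEntry(
            mood,
            frozenset(pair_patterns.get(mood, set())),
            frozenset(rule_patterns.get(mood, set())),
        )
        for mood in sorted(set(pair_patterns) | set(rule_patterns), key=mood_rank)
    ]
    return ConflictReport(entries)
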