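"""Read tabular pose-observation streams and attach them to the ontology.

The expected schema mirrors the study's observation sheets: one row per
second of video with columns ``time``, ``pose``, ``status`` and optionally
``scene`` and ``patient``.  Pose is recorded as a numeric code (default
1 = walking, 2 = sitting, 3 = standing) translated to the pose letters
C/S/P through a configurable PoseCodeMap.  Recorded status values are kept
verbatim as ground-truth labels for evaluation, never re-derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd

from alzmood.labels import LETTER_TO_PATTERN, POSE_LETTERS, Mood
from alzmood.ontology import OntologyModel, OntologyError

#: Status spellings that map onto the mood vocabulary (case-insensitive).
KNOWN_STATUS = {
    "wander": Mood.WANDERING,
    "wandering": Mood.WANDERING,
    "nervous": Mood.NERVOUS,
    "depressed": Mood.DEPRESSED,
    "disoriented": Mood.DISORIENTED,
    "bored": Mood.BORED,
    "boring": Mood.BORED,
    "none": Mood.NONE,
    "nothing": Mood.NONE,
    "no observation": Mood.NONE,
}


@dataclass(frozen=True)
class PoseCodeMap:
    """Injective numeric-code -> pose-letter mapping."""

    mapping: dict[int, str] = field(default_factory=lambda: {1: "C", 2: "S", 3: "P"})

    def __post_init__(self) -> None:
        letters = list(self.mapping.values())
        if sorted(set(letters)) != sorted(set(POSE_LETTERS)) or len(letters) != len(set(letters)):
            raise ValueError(
                f"code map must be injective onto {POSE_LETTERS}, got {self.mapping}"
            )

    def decode(self, code) -> str:
        key = int(code)
        if key not in self.mapping:
            raise KeyError(key)
        return self.mapping[key]

    def encode(self, letter: str) -> int:
        for code, let in self.mapping.items():
            if let == letter:
                return code
        raise KeyError(letter)


DEFAULT_CODE_MAP = PoseCodeMap()


@dataclass(frozen=True)
class PoseEvent:
    """One pose observation: time (seconds from stream start) and pose letter."""

    t: int
    pose: str
    status: str | None = None
    scene: str | None = None
    patient_id: str = "patient_1"

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"event time must be non-negative, got {self.t}")
        if self.pose not in POSE_LETTERS:
            raise ValueError(f"invalid pose letter {self.pose!r}")

    @property
    def pattern(self) -> str:
        """Activity pattern name (walking / sitting / standing)."""
        return LETTER_TO_PATTERN[self.pose]


@dataclass
class PoseStream:
    """Time-ordered pose observations for a single patient."""

    patient_id: str
    events: list[PoseEvent]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.t <= prev.t:
                raise ValueError(
                    f"stream {self.patient_id!r}: event times must be strictly "
                    f"increasing ({prev.t} then {cur.t})"
                )
        for ev in self.events:
            if ev.patient_id != self.patient_id:
                raise ValueError(
                    f"event patient {ev.patient_id!r} != stream patient {self.patient_id!r}"
                )

    @property
    def letters(self) -> str:
        """The stream's pose letters as one string."""
        return "".join(ev.pose for ev in self.events)


def parse_time(value) -> int:
    """Parse H:MM:SS-style timestamps or bare integers to seconds."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if float(value) != int(value):
            raise ValueError(f"non-integer time value {value!r}")
        return int(value)
    text = str(value).strip()
    if ":" in text:
        parts = text.split(":")
        if len(parts) > 3 or any(not p.isdigit() for p in parts):
            raise ValueError(f"cannot parse time {value!r}")
        secs = 0
        for p in parts:
            secs = secs * 60 + int(p)
        return secs
    if not text.lstrip("-").isdigit():
        raise ValueError(f"cannot parse time {value!r}")
    return int(text)


_DEFAULT_COLUMNS = {
    "time": "time",
    "pose": "pose",
    "status": "status",
    "scene": "scene",
    "patient": "patient",
}


def _resolve_columns(df: pd.DataFrame, columns: Mapping[str, str]) -> dict[str, str | None]:
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str | None] = {}
    for role, wanted in columns.items():
        resolved[role] = lower.get(wanted.lower())
    for role in ("time", "pose"):
        if resolved[role] is None:
            raise ValueError(f"required column {columns[role]!r} ({role}) not found in {list(df.columns)}")
    return resolved


def read_pose_table(
    file: Union[str, Path],
    code_map: PoseCodeMap = DEFAULT_CODE_MAP,
    columns: Mapping[str, str] | None = None,
) -> list[PoseStream]:
    """Read a CSV/XLSX observation table into per-patient pose streams.

    Rows are grouped by the optional patient column (single implicit patient
    otherwise) and sorted by time within a patient.  Pose values may be
    numeric codes (decoded through ``code_map``) or pose letters.  Unknown
    status strings are preserved verbatim with a warning; unmapped pose
    codes and non-monotone/duplicate times are errors naming the row.
    """
    path = Path(file)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    cols = _resolve_columns(df, {**_DEFAULT_COLUMNS, **(columns or {})})

    records: dict[str, list[PoseEvent]] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based plus header
        raw_pose = row[cols["pose"]]
        if isinstance(raw_pose, str) and raw_pose.strip().upper() in POSE_LETTERS:
            pose = raw_pose.strip().upper()
        else:
            try:
                pose = code_map.decode(raw_pose)
            except (KeyError, TypeError, ValueError):
                raise ValueError(f"row {rowno}: unmapped pose code {raw_pose!r}") from None
        try:
            t = parse_time(row[cols["time"]])
        except ValueError as exc:
            raise ValueError(f"row {rowno}: {exc}") from None
        status = None
        if cols["status"] is not None and not pd.isna(row[cols["status"]]):
            status = str(row[cols["status"]]).strip()
            if status.lower() not in KNOWN_STATUS:
                warnings.warn(
                    f"row {rowno}: unknown status {status!r} preserved verbatim",
                    stacklevel=2,
                )
        scene = None
        if cols["scene"] is not None and not pd.isna(row[cols["scene"]]):
            scene = str(row[cols["scene"]]).strip()
        patient = "patient_1"
        if cols["patient"] is not None and not pd.isna(row[cols["patient"]]):
            patient = str(row[cols["patient"]]).strip()
        records.setdefault(patient, []).append(
            PoseEvent(t=t, pose=pose, status=status, scene=scene, patient_id=patient)
        )

    streams: list[PoseStream] = []
    for patient, events in records.items():
        events.sort(key=lambda e: e.t)
        for prev, cur in zip(events, events[1:]):
            if cur.t == prev.t:
                raise ValueError(
                    f"patient {patient!r}: duplicate timestamp {cur.t}"
                )
        streams.append(PoseStream(patient_id=patient, events=events))
    streams.sort(key=lambda s: s.patient_id)
    return streams


#: Pattern-class label used when typing observation individuals.
_PATTERN_CLASS = {"C": "Walking", "S": "Sitting", "P": "Standing"}


def attach_individuals(model: OntologyModel, streams: Sequence[PoseStream]) -> OntologyModel:
    """Attach streams to the schema as individuals (in place).

    One Patient individual per stream and one observation individual per
    event, typed by its activity-pattern subclass.  The model must contain
    the ``Patient`` class and the three Pattern subclasses.
    """
    required = ["Patient"] + sorted(set(_PATTERN_CLASS.values()))
    for cls in required:
        if cls not in model.classes:
            raise OntologyError(f"schema class {cls!r} missing from model")
    for stream in streams:
        model.add_individual(stream.patient_id, "Patient")
        for ev in stream.events:
            model.add_individual(f"{stream.patient_id}_obs_{ev.t}", _PATTERN_CLASS[ev.pose])
    return model
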