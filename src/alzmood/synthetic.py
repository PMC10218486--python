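"""Seeded synthetic cohorts and pose streams with known ground truth.

The generator emulates the study conditions: a cohort of 147 patients of
both sexes (men aged 75-86, women aged 75-89) observed for one minute at
one pose per second, so the default stream length is 60 events.  Each
stream is built from its true mood's canonical template (wandering ->
walking runs, depressed -> sitting runs, none -> standing runs, nervous /
disoriented / bored -> the corresponding alternations) and corrupted by
i.i.d. substitution noise; insertions and deletions are excluded because
the observation grid is fixed-rate.

A "video" preset with 45 patients mirrors the recorded subset of the
cohort; neither preset is privileged by the code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from alzmood.classifier import DEFAULT_TEMPLATES, CanonicalPattern
from alzmood.ingest import DEFAULT_CODE_MAP, PoseCodeMap, PoseEvent, PoseStream
from alzmood.labels import Mood, POSE_LETTERS

#: Named cohort sizes: the full study population and the recorded subset.
COHORT_PRESETS = {"full": 147, "video": 45}


@dataclass(frozen=True)
class CohortConfig:
    """Demographic parameters of a synthetic cohort.

    Ages are sampled uniformly within the sex-specific inclusive ranges;
    ``sex_ratio`` is the fraction of male patients.
    """

    n_patients: int = 147
    sex_ratio: float = 0.5
    male_age_range: tuple[int, int] = (75, 86)
    female_age_range: tuple[int, int] = (75, 89)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        for lo, hi in (self.male_age_range, self.female_age_range):
            if lo > hi:
                raise ValueError(f"invalid age range ({lo}, {hi})")


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str  # "M" or "F"
    age: int


@dataclass(frozen=True)
class StreamConfig:
    """Parameters of one synthetic pose stream."""

    true_mood: Mood
    length: int = 60
    noise_rate: float = 0.0
    seed: int = 0
    patient_id: str = "patient_1"

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("stream length must be >= 2")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")


@dataclass
class LabeledDataset:
    """Streams with ground-truth moods and the proportions that produced them."""

    streams: list[PoseStream]
    labels: dict[str, Mood]
    mixing_proportions: dict[Mood, float]

    def __len__(self) -> int:
        return len(self.streams)


def generate_cohort(config: CohortConfig = CohortConfig()) -> list[Patient]:
    """Sample a cohort; same config (including seed) -> identical cohort."""
    rng = np.random.default_rng(config.seed)
    patients = []
    width = max(3, len(str(max(config.n_patients, 1))))
    for i in range(config.n_patients):
        male = rng.random() < config.sex_ratio
        lo, hi = config.male_age_range if male else config.female_age_range
        age = int(rng.integers(lo, hi + 1))
        patients.append(
            Patient(patient_id=f"patient_{i + 1:0{width}d}", sex="M" if male else "F", age=age)
        )
    return patients


def _template_for(mood: Mood, templates: Sequence[CanonicalPattern]) -> CanonicalPattern:
    for pat in templates:
        if pat.mood == mood:
            return pat
    raise ValueError(f"no canonical template for mood {mood}")


def generate_stream(
    config: StreamConfig,
    templates: Sequence[CanonicalPattern] = DEFAULT_TEMPLATES,
) -> PoseStream:
    """Tile the mood's template to length, then apply substitution noise.

    Each event is independently replaced, with probability ``noise_rate``,
    by a uniformly random *other* pose letter.  Times run 1..length (one
    event per second, matching the observation-sheet convention).
    """
    rng = np.random.default_rng(config.seed)
    base = _template_for(config.true_mood, templates).tiled(config.length)
    letters = []
    for ch in base:
        if rng.random() < config.noise_rate:
            others = [l for l in POSE_LETTERS if l != ch]
            ch = others[int(rng.integers(len(others)))]
        letters.append(ch)
    events = [
        PoseEvent(
            t=i + 1,
            pose=ch,
            status=config.true_mood.value,
            patient_id=config.patient_id,
        )
        for i, ch in enumerate(letters)
    ]
    return PoseStream(patient_id=config.patient_id, events=events)


def generate_dataset(
    cohort: Sequence[Patient],
    mixing_proportions: Mapping[Mood, float],
    stream_config: StreamConfig = StreamConfig(true_mood=Mood.NONE),
    seed: int = 0,
) -> LabeledDataset:
    """Assign each patient a true mood multinomially and generate one stream each.

    ``stream_config`` supplies length/noise; its mood, seed and patient id
    are overridden per patient.  Proportions must sum to 1.
    """
    total = float(sum(mixing_proportions.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixing proportions sum to {total}, expected 1")
    moods = list(mixing_proportions)
    probs = np.asarray([mixing_proportions[m] for m in moods], dtype=float)
    rng = np.random.default_rng(seed)
    assignments = rng.choice(len(moods), size=len(cohort), p=probs)
    streams: list[PoseStream] = []
    labels: dict[str, Mood] = {}
    for patient, k in zip(cohort, assignments):
        mood = moods[int(k)]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(
            stream_config, true_mood=mood, seed=sub_seed, patient_id=patient.patient_id
        )
        streams.append(generate_stream(cfg))
        labels[patient.patient_id] = mood
    return LabeledDataset(
        streams=streams, labels=labels, mixing_proportions=dict(mixing_proportions)
    )


def write_pose_csv(
    streams: Sequence[PoseStream],
    path: Union[str, Path],
    code_map: PoseCodeMap = DEFAULT_CODE_MAP,
) -> None:
    """Write streams in the observation-sheet schema (time,pose,status,scene,patient).

    Times are written as integer seconds and poses as numeric codes, so the
    output flows through ``read_pose_table`` unchanged.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "pose", "status", "scene", "patient"])
        for stream in streams:
            for ev in stream.events:
                writer.writerow(
                    [ev.t, code_map.encode(ev.pose), ev.status or "", ev.scene or "", ev.patient_id]
                )
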