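"""Shared fixtures: ontology models, letter-string streams, observation sheets."""

from __future__ import annotations

import csv

import pytest

from alzmood import (
    OntologyModel,
    PoseEvent,
    PoseStream,
    build_schema,
    build_taxonomy,
    load_taxonomy_fixture,
)


def stream_from_letters(letters: str, patient_id: str = "patient_1") -> PoseStream:
    """Build a one-event-per-second stream from a pose-letter string."""
    events = [
        PoseEvent(t=i + 1, pose=ch, patient_id=patient_id)
        for i, ch in enumerate(letters)
    ]
    return PoseStream(patient_id=patient_id, events=events)


@pytest.fixture(scope="session")
def taxonomy_model() -> OntologyModel:
    """The full 7-class / 36-subclass observational taxonomy."""
    return build_taxonomy(load_taxonomy_fixture("taxonomy_full"))


@pytest.fixture(scope="session")
def schema_model() -> OntologyModel:
    """The operational Patient/Scene/Pattern/State schema with properties."""
    return build_schema()


#: Synthetic 12-row observation sheet in the study's spreadsheet layout
#: (H:MM:SS times, numeric pose codes, recorded status).  The source sheet
#: elides the middle of the minute; row 6 here is a constructed stand-in so
#: the excerpt has twelve concrete rows.
OBSERVATION_ROWS = [
    ("0:00:1", 1, "Wander"),
    ("0:00:2", 2, "Wander"),
    ("0:00:3", 3, "Nervous"),
    ("0:00:4", 1, "Depressed"),
    ("0:00:5", 1, "Depressed"),
    ("0:00:30", 2, "Depressed"),
    ("0:00:55", 2, "Depressed"),
    ("0:00:56", 2, "Depressed"),
    ("0:00:57", 2, "Nervous"),
    ("0:00:58", 1, "Nervous"),
    ("0:00:59", 1, "Depressed"),
    ("0:00:60", 1, "Depressed"),
]


@pytest.fixture
def observation_csv(tmp_path):
    """Write the 12-row synthetic observation sheet to a CSV file."""
    path = tmp_path / "observations.csv"
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "pose", "status"])
        writer.writerows(OBSERVATION_ROWS)
    return path
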