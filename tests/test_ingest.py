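"""Tabular ingestion and individual attachment."""

import csv
import random

import pandas as pd
import pytest

from alzmood import (
    PoseCodeMap,
    PoseEvent,
    PoseStream,
    attach_individuals,
    build_schema,
    parse_ontology,
    read_pose_table,
    serialize_ontology,
)
from alzmood.ingest import parse_time
from alzmood.ontology import OntologyError

from .conftest import OBSERVATION_ROWS


class TestTimeParsing:
    @pytest.mark.parametrize(
        "value,expected",
        [("0:00:1", 1), ("0:00:60", 60), ("0:01:05", 65), ("1:00:00", 3600), (7, 7), ("42", 42)],
    )
    def test_formats(self, value, expected):
        assert parse_time(value) == expected

    @pytest.mark.parametrize("value", ["abc", "1:xx:3", "1.5.2", -1])
    def test_rejects_garbage(self, value):
        with pytest.raises(ValueError):
            if isinstance(value, int):
                PoseEvent(t=value, pose="C")
            else:
                parse_time(value)


class TestReadPoseTable:
    def test_observation_sheet_one_stream(self, observation_csv):
        streams = read_pose_table(observation_csv)
        assert len(streams) == 1
        (stream,) = streams
        assert len(stream.events) == 12
        assert stream.letters == "CSPCCSSSSCCC"
        assert stream.events[0].status == "Wander"
        assert [e.t for e in stream.events[:3]] == [1, 2, 3]

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("time,pose,status\n", encoding="utf-8")
        assert read_pose_table(path) == []

    def test_unmapped_pose_code_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,pose,status\n1,1,\n2,9,\n", encoding="utf-8")
        with pytest.raises(ValueError, match="row 3.*9"):
            read_pose_table(path)

    def test_duplicate_timestamp_is_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("time,pose\n5,1\n5,2\n", encoding="utf-8")
        with pytest.raises(ValueError, match="duplicate timestamp 5"):
            read_pose_table(path)

    def test_row_shuffle_stability(self, tmp_path):
        rows = list(OBSERVATION_ROWS)
        rng = random.Random(0)
        shuffled = rows[:]
        rng.shuffle(shuffled)
        paths = []
        for name, data in (("a.csv", rows), ("b.csv", shuffled)):
            path = tmp_path / name
            with open(path, "w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh)
                w.writerow(["time", "pose", "status"])
                w.writerows(data)
            paths.append(path)
        a, b = (read_pose_table(p) for p in paths)
        assert [e for s in a for e in s.events] == [e for s in b for e in s.events]

    def test_unknown_status_warns_and_is_preserved(self, tmp_path):
        path = tmp_path / "odd.csv"
        path.write_text("time,pose,status\n1,1,Perplexed\n2,2,\n", encoding="utf-8")
        with pytest.warns(UserWarning, match="Perplexed"):
            streams = read_pose_table(path)
        assert streams[0].events[0].status == "Perplexed"

    def test_xlsx_and_custom_code_map(self, tmp_path):
        path = tmp_path / "obs.xlsx"
        pd.DataFrame(
            {"Time": [1, 2], "Pose": [10, 30], "Status": ["Wander", None],
             "Patient": ["p7", "p7"]}
        ).to_excel(path, index=False)
        streams = read_pose_table(path, code_map=PoseCodeMap({10: "C", 20: "S", 30: "P"}))
        assert streams[0].patient_id == "p7"
        assert streams[0].letters == "CP"

    def test_multiple_patients_split(self, tmp_path):
        path = tmp_path / "multi.csv"
        path.write_text(
            "time,pose,patient\n1,1,a\n1,2,b\n2,3,a\n", encoding="utf-8"
        )
        streams = read_pose_table(path)
        assert [s.patient_id for s in streams] == ["a", "b"]
        assert streams[0].letters == "CP"

    def test_non_injective_code_map_rejected(self):
        with pytest.raises(ValueError, match="injective"):
            PoseCodeMap({1: "C", 2: "C", 3: "P"})


class TestAttachIndividuals:
    def test_counts(self, observation_csv):
        model = build_schema()
        streams = read_pose_table(observation_csv)
        before = len(model.individuals)
        attach_individuals(model, streams)
        assert len(model.individuals) - before == 1 + 12

    def test_pattern_typing_follows_letters(self, observation_csv):
        model = build_schema()
        (stream,) = read_pose_table(observation_csv)
        attach_individuals(model, [stream])
        want = {"C": "Walking", "S": "Sitting", "P": "Standing"}
        for ev in stream.events:
            name = f"{stream.patient_id}_obs_{ev.t}"
            assert model.individual_class(name) == want[ev.pose]

    def test_no_streams_leaves_model_unchanged(self, schema_model):
        snapshot = schema_model.logical_content()
        attach_individuals(schema_model, [])
        assert schema_model.logical_content() == snapshot

    def test_missing_schema_class_is_error(self, taxonomy_model):
        stream = PoseStream("p", [PoseEvent(t=1, pose="C", patient_id="p")])
        with pytest.raises(OntologyError, match="missing"):
            attach_individuals(taxonomy_model, [stream])

    def test_individuals_survive_owl_round_trip(self, observation_csv):
        model = build_schema()
        attach_individuals(model, read_pose_table(observation_csv))
        back = parse_ontology(serialize_ontology(model, "turtle"))
        assert back.individuals == model.individuals
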