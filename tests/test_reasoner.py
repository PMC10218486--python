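"""Rule firing, thresholds, instance checking, and the source audit."""

import pytest
from hypothesis import given, settings, strategies as st

from alzmood import (
    DEFAULT_RULES,
    Mood,
    PairCodeTable,
    PoseEvent,
    PoseStream,
    apply_state_rules,
    attach_individuals,
    audit_rule_consistency,
    build_schema,
    instance_check,
    is_subclass_of,
    min_trigger_run,
    read_pose_table,
)
from alzmood.labels import PATTERN_TO_LETTER
from alzmood.ontology import OntologyError
from alzmood.reasoner import ConflictReport, StateRule

from .conftest import stream_from_letters


class TestApplyStateRules:
    def test_four_walking_events_assert_wandering(self):
        result = apply_state_rules(stream_from_letters("CCCC"))
        assert Mood.WANDERING in result.asserted_states

    def test_three_walking_events_do_not(self):
        result = apply_state_rules(stream_from_letters("CCC"))
        assert Mood.WANDERING not in result.asserted_states

    def test_interrupted_run_does_not_count_consecutively(self):
        # Two walking runs of 2 and 2, split by sitting: no wandering.
        result = apply_state_rules(stream_from_letters("CCSCC"))
        assert Mood.WANDERING not in result.asserted_states

    def test_interrupted_run_counts_under_nonconsecutive_flag(self):
        result = apply_state_rules(stream_from_letters("CCSCC"), consecutive=False)
        assert Mood.WANDERING in result.asserted_states

    def test_empty_stream_asserts_nothing(self):
        result = apply_state_rules(PoseStream("p", []))
        assert result.asserted_states == set()
        assert result.firings == []

    def test_multiple_moods_may_fire(self):
        result = apply_state_rules(stream_from_letters("SCCCC"))
        # sitting fires depressed/bored/disoriented/nervous; the walking
        # run of 4 fires wandering; nothing is exclusive by default.
        assert Mood.WANDERING in result.asserted_states
        assert Mood.DEPRESSED in result.asserted_states
        assert result.primary_state is Mood.WANDERING

    def test_every_firing_meets_its_threshold(self):
        result = apply_state_rules(stream_from_letters("CCCCSSP"))
        for firing in result.firings:
            assert firing.run_length >= firing.rule.min_repetitions

    @given(st.text(alphabet="CSP", min_size=0, max_size=20),
           st.text(alphabet="CSP", min_size=1, max_size=10))
    @settings(deadline=None, max_examples=150)
    def test_monotone_in_data(self, prefix, suffix):
        before = apply_state_rules(stream_from_letters(prefix)).asserted_states
        after = apply_state_rules(stream_from_letters(prefix + suffix)).asserted_states
        assert before <= after

    @pytest.mark.parametrize("rule", DEFAULT_RULES, ids=lambda r: r.mood.value)
    def test_threshold_boundary(self, rule):
        letter = PATTERN_TO_LETTER[sorted(rule.allowed_patterns)[0]]
        at = apply_state_rules(stream_from_letters(letter * rule.min_repetitions))
        assert rule.mood in at.asserted_states
        if rule.min_repetitions > 1:
            below = apply_state_rules(
                stream_from_letters(letter * (rule.min_repetitions - 1))
            )
            assert rule.mood not in below.asserted_states


class TestMinTriggerRun:
    def test_wandering_needs_four(self):
        assert min_trigger_run(Mood.WANDERING) == 4

    @pytest.mark.parametrize(
        "mood", [Mood.DEPRESSED, Mood.BORED, Mood.DISORIENTED, Mood.NERVOUS]
    )
    def test_single_observation_moods(self, mood):
        assert min_trigger_run(mood) == 1

    def test_missing_mood_is_error(self):
        with pytest.raises(ValueError, match="no rule"):
            min_trigger_run(Mood.NONE)

    def test_probing_respects_custom_rules(self):
        rules = [StateRule(Mood.BORED, frozenset({"standing"}), 7)]
        assert min_trigger_run(Mood.BORED, rules) == 7


class TestInstanceCheck:
    @pytest.fixture
    def populated(self, observation_csv):
        model = build_schema()
        attach_individuals(model, read_pose_table(observation_csv))
        return model

    def test_walking_observation_is_a_pattern(self, populated):
        assert instance_check(populated, "patient_1_obs_1", "Pattern")

    def test_own_asserted_class(self, populated):
        assert instance_check(populated, "patient_1_obs_1", "Walking")

    def test_walking_observation_is_not_a_state(self, populated):
        assert not instance_check(populated, "patient_1_obs_1", "State")

    def test_unknown_names_error(self, populated):
        with pytest.raises(OntologyError):
            instance_check(populated, "ghost", "Pattern")
        with pytest.raises(OntologyError):
            instance_check(populated, "patient_1_obs_1", "Ghost")

    def test_agrees_with_subsumption_of_asserted_type(self, populated):
        for name, asserted in populated.individuals:
            for cls in populated.classes:
                assert instance_check(populated, name, cls) == is_subclass_of(
                    populated, asserted, cls
                )


class TestAudit:
    def test_nervous_flagged(self):
        report = audit_rule_consistency()
        entry = {e.mood: e for e in report.entries}[Mood.NERVOUS]
        assert not entry.agree
        assert entry.pair_table_patterns == frozenset({"walking", "sitting"})
        assert entry.rule_patterns == frozenset({"sitting", "standing"})

    def test_depressed_and_wandering_agree(self):
        by_mood = {e.mood: e for e in audit_rule_consistency().entries}
        assert by_mood[Mood.DEPRESSED].agree
        assert by_mood[Mood.WANDERING].agree
        assert by_mood[Mood.BORED].agree

    def test_none_only_in_pair_table(self):
        by_mood = {e.mood: e for e in audit_rule_consistency().entries}
        assert by_mood[Mood.NONE].rule_patterns == frozenset()
        assert not by_mood[Mood.NONE].agree

    def test_empty_sources_empty_report(self):
        table = PairCodeTable()
        report = audit_rule_consistency(table, rules=[])
        assert all(e.rule_patterns == frozenset() for e in report.entries)
        empty = ConflictReport(entries=[])
        assert empty.disagreements() == []

    def test_text_rendering_mentions_every_mood(self):
        text = audit_rule_consistency().to_text()
        for mood in (Mood.WANDERING, Mood.NERVOUS, Mood.NONE):
            assert mood.value in text
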