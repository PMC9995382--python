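import pytest

from interviewsim.featurize import FeaturizerConfig, extract_ngrams
from interviewsim.rules import (
    ClassifiedQuestion,
    DialogueContext,
    RuleConfig,
    SuggestiveKeyword,
    classify,
    detect_repetition,
    match_greeting,
    suggestive_override,
    tag_topics,
    tune_jaccard_threshold,
)
from interviewsim.synthcorpus import default_rule_config
from interviewsim.taxonomy import GREETING, Category, QuestionType


@pytest.fixture
def cfg():
    return default_rule_config()


class TestGreeting:
    def test_hello_matches(self, cfg):
        assert match_greeting("Hello", cfg)
        assert match_greeting("hello!", cfg)
        assert match_greeting("How old are you?", cfg)

    def test_substantive_question_does_not_match(self, cfg):
        assert not match_greeting("Tell me everything that happened", cfg)

    def test_empty_pattern_list_never_matches(self):
        cfg = RuleConfig(greeting_patterns=())
        assert not match_greeting("Hello", cfg)


class TestRepetition:
    FC = FeaturizerConfig()

    def test_first_question_never_flagged(self, cfg):
        ctx = DialogueContext()
        feats = extract_ngrams("Did you go to the park?", self.FC)
        assert not detect_repetition(feats, ctx, cfg)

    def test_identical_consecutive_flagged(self, cfg):
        feats = extract_ngrams("Did you go to the park?", self.FC)
        ctx = DialogueContext(previous_question_features=dict(feats))
        assert detect_repetition(feats, ctx, cfg)

    def test_below_threshold_not_flagged(self):
        cfg = RuleConfig(jaccard_threshold=0.5)
        a = {"ab": 1, "bc": 1}
        b = {"bc": 1, "cd": 1}  # jaccard 1/3
        ctx = DialogueContext(previous_question_features=a)
        assert not detect_repetition(b, ctx, cfg)

    def test_only_immediately_preceding_question_counts(self, cfg):
        q1 = extract_ngrams("Did you go to the park?", self.FC)
        q2 = extract_ngrams("Tell me about your family", self.FC)
        ctx = DialogueContext()
        ctx.advance(q1)
        ctx.advance(q2)
        # q1 again: two turns back, so not a repetition of q2
        assert not detect_repetition(q1, ctx, cfg)

    def test_frequency_insensitive(self, cfg):
        ctx = DialogueContext(previous_question_features={"ab": 7, "bc": 2})
        assert detect_repetition({"ab": 1, "bc": 100}, ctx, cfg)

    def test_threshold_tuner_separates_labeled_pairs(self):
        pairs = [
            ("did you go to the park", "did you go to the park", True),
            ("did you go to the park", "so, did you go to the park", True),
            ("did you go to the park", "tell me about your family", False),
            ("tell me what happened", "who was with you", False),
        ]
        t, acc = tune_jaccard_threshold(pairs)
        assert acc == 1.0
        assert 0 < t <= 1


class TestSuggestiveOverride:
    def test_undisclosed_harm_recodes_to_unspecific_suggestive(self, cfg):
        ctx = DialogueContext()
        out = suggestive_override(
            "Tell me about someone hurting you", QuestionType.INVITATION_FOCUS, ctx, cfg
        )
        assert out is QuestionType.UNSPECIFIC_SUGGESTIVE

    def test_after_disclosure_model_label_kept(self, cfg):
        ctx = DialogueContext(mentioned_topics={"incident"})
        out = suggestive_override(
            "Tell me about someone hurting you", QuestionType.INVITATION_FOCUS, ctx, cfg
        )
        assert out is QuestionType.INVITATION_FOCUS

    def test_no_keyword_no_change(self, cfg):
        ctx = DialogueContext()
        out = suggestive_override(
            "Tell me about your family", QuestionType.INVITATION_FOCUS, ctx, cfg
        )
        assert out is QuestionType.INVITATION_FOCUS

    def test_never_changes_not_recommended_labels(self, cfg):
        ctx = DialogueContext()
        for qt in QuestionType:
            if qt.category is Category.NOT_RECOMMENDED:
                out = suggestive_override("Did he hurt you?", qt, ctx, cfg)
                assert out is qt

    def test_unlinked_keyword_always_triggers(self):
        cfg = RuleConfig(suggestive_keywords=(SuggestiveKeyword("hurt", None),))
        ctx = DialogueContext(mentioned_topics={"incident"})
        out = suggestive_override(
            "Tell me about someone hurting you", QuestionType.INVITATION_FOCUS, ctx, cfg
        )
        assert out is QuestionType.UNSPECIFIC_SUGGESTIVE


class TestTopicTagging:
    def test_recommended_question_tagged(self, cfg):
        assert tag_topics("Tell me about your dad", QuestionType.INVITATION_FOCUS, cfg) == ["dad"]

    def test_not_recommended_question_never_tagged(self, cfg):
        assert tag_topics("Did your dad hurt you?", QuestionType.SPECIFIC_SUGGESTIVE, cfg) == []

    def test_greeting_never_tagged(self, cfg):
        assert tag_topics("Hello dad", GREETING, cfg) == []

    def test_two_topics_in_config_order(self, cfg):
        out = tag_topics(
            "Tell me about your dad and your mom", QuestionType.INVITATION_FOCUS, cfg
        )
        assert out == ["dad", "mom"]


class TestClassifyPathway:
    def test_greeting_at_turn_zero(self, small_model, cfg):
        ctx = DialogueContext()
        cq = classify("Hello", ctx, small_model, cfg)
        assert cq.qtype == GREETING
        assert cq.source == "greeting_rule"
        assert cq.category is None
        assert cq.topics == []

    def test_consecutive_duplicate_is_repetition(self, small_model, cfg):
        ctx = DialogueContext()
        q = "Do you play with dad?"
        cq1 = classify(q, ctx, small_model, cfg)
        ctx.advance(cq1.features)
        cq2 = classify(q, ctx, small_model, cfg)
        assert cq2.qtype is QuestionType.REPETITION
        assert cq2.source == "repetition_rule"

    def test_invitation_broad_template_classified(self, small_model, cfg):
        ctx = DialogueContext()
        cq = classify(
            "Tell me everything that happened from the beginning to the end",
            ctx, small_model, cfg,
        )
        assert cq.qtype is QuestionType.INVITATION_BROAD
        assert cq.source == "model"

    def test_exactly_one_label_and_source_per_utterance(self, small_model, cfg):
        ctx = DialogueContext()
        probes = [
            "Hello",
            "Tell me everything that happened from the beginning to the end",
            "Did your dad hurt you?",
            "Was it the park or the garden?",
        ]
        for text in probes:
            cq = classify(text, ctx, small_model, cfg)
            assert cq.source in {"greeting_rule", "repetition_rule", "model", "suggestive_override"}
            assert cq.qtype == GREETING or isinstance(cq.qtype, QuestionType)
            ctx.advance(cq.features)

    def test_repetition_iff_repetition_rule_source(self, small_model, cfg):
        ctx = DialogueContext()
        q = "Tell me about your family"
        cq1 = classify(q, ctx, small_model, cfg)
        ctx.advance(cq1.features)
        cq2 = classify(q, ctx, small_model, cfg)
        assert (cq2.qtype is QuestionType.REPETITION) == (cq2.source == "repetition_rule")
        assert cq2.qtype is QuestionType.REPETITION

    def test_classify_is_pure_wrt_context(self, small_model, cfg):
        ctx = DialogueContext()
        before = (set(ctx.mentioned_topics), ctx.turn_index)
        classify("Tell me about your dad", ctx, small_model, cfg)
        assert (set(ctx.mentioned_topics), ctx.turn_index) == before


def test_rule_config_yaml_round_trip(tmp_path, cfg):
    path = tmp_path / "rules.yaml"
    cfg.to_yaml(str(path))
    loaded = RuleConfig.from_yaml(str(path))
    assert loaded == cfg


def test_jaccard_threshold_validation():
    with pytest.raises(ValueError):
        RuleConfig(jaccard_threshold=0.0)
    with pytest.raises(ValueError):
        RuleConfig(jaccard_threshold=1.5)
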