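import numpy as np
import pytest

from interviewsim.avatar import (
    AvatarMemory,
    AvatarProfile,
    AvatarResponse,
    ScenarioPack,
    build_default_packs,
    build_roster,
    build_scenario_pack,
    case_ground_truth,
    draw_answer_kind,
    respond,
)
from interviewsim.rules import ClassifiedQuestion
from interviewsim.taxonomy import GREETING, Category, QuestionType, category_of


def _cq(qtype, text="Tell me more", topics=None):
    cat = None if qtype == GREETING else category_of(qtype)
    return ClassifiedQuestion(
        text=text, features={}, qtype=qtype, category=cat, topics=topics or []
    )


class TestRoster:
    def test_sixteen_avatars_eight_patterns(self):
        roster = build_roster(seed=0)
        assert len(roster) == 16
        patterns = {(p.age, p.gender, p.abused) for p in roster}
        assert len(patterns) == 8
        for pattern in patterns:
            assert sum((p.age, p.gender, p.abused) == pattern for p in roster) == 2

    def test_two_reserved_fourteen_available(self):
        roster = build_roster(seed=1)
        reserved = [p for p in roster if p.reserved_for_modeling]
        assert len(reserved) == 2
        assert len([p for p in roster if not p.reserved_for_modeling]) == 14
        assert {(p.age, p.gender, p.abused) for p in reserved} == {
            (4, "boy", False),
            (6, "girl", True),
        }

    def test_ids_unique(self):
        roster = build_roster(seed=2)
        assert len({p.avatar_id for p in roster}) == 16

    def test_elicitation_probability_tied_to_age(self):
        for p in build_roster(seed=0):
            assert p.p_elicit == (0.20 if p.age == 4 else 0.25)


class TestMemoryModel:
    def test_exactly_nine_details_last_four_conclusive(self, pack4):
        m = pack4.fresh_memory()
        emitted = []
        while not m.exhausted:
            emitted.append(m.emit_relevant())
        texts = [t for t, _ in emitted]
        flags = [c for _, c in emitted]
        assert len(texts) == 9
        assert len(set(texts)) == 9
        assert flags == [False] * 5 + [True] * 4

    def test_memory_requires_nine_details(self):
        with pytest.raises(ValueError):
            AvatarMemory(relevant_details=["only", "five", "details", "is", "wrong"])

    def test_details_emitted_in_fixed_order_at_most_once(self, pack4):
        m = pack4.fresh_memory()
        first = [m.emit_relevant()[0] for _ in range(3)]
        assert first == m.relevant_details[:3]
        with pytest.raises(RuntimeError):
            m2 = pack4.fresh_memory()
            for _ in range(10):
                m2.emit_relevant()

    def test_topic_responses_in_presentation_order(self, pack4):
        m = pack4.fresh_memory()
        dad = list(m.topic_responses["dad"])
        got = [m.next_topic_response(["dad"]) for _ in range(len(dad) + 1)]
        assert got[:-1] == dad
        assert got[-1] is None  # exhausted

    def test_case_ground_truth(self, pack4, pack6):
        gt_a = case_ground_truth(pack4.profile, pack4.memory_template)
        gt_n = case_ground_truth(pack6.profile, pack6.memory_template)
        assert gt_a["abuse"] == "present"
        assert gt_n["abuse"] == "absent"
        assert len(gt_a["conclusive_details"]) == 4
        assert len(gt_n["conclusive_details"]) == 4
        assert gt_a["conclusive_details"] == pack4.memory_template.relevant_details[-4:]


class TestDrawAnswerKind:
    def test_recommended_kinds_only(self, pack4, rng):
        m = pack4.fresh_memory()
        kinds = {
            draw_answer_kind(QuestionType.INVITATION_BROAD, pack4.profile, m, rng)
            for _ in range(300)
        }
        assert kinds <= {"relevant", "neutral", "none"}

    def test_not_recommended_kinds_only(self, pack4, rng):
        m = pack4.fresh_memory()
        kinds = {
            draw_answer_kind(QuestionType.SPECIFIC_SUGGESTIVE, pack4.profile, m, rng)
            for _ in range(300)
        }
        assert kinds <= {"incorrect", "none"}

    def test_exhausted_memory_never_yields_relevant(self, pack4, rng):
        m = pack4.fresh_memory()
        while not m.exhausted:
            m.emit_relevant()
        kinds = {
            draw_answer_kind(QuestionType.DIRECTIVE, pack4.profile, m, rng)
            for _ in range(300)
        }
        assert "relevant" not in kinds

    def test_greeting_never_yields_detail(self, pack4, rng):
        assert draw_answer_kind(GREETING, pack4.profile, pack4.fresh_memory(), rng) == "none"

    @pytest.mark.parametrize("age,p", [(4, 0.20), (6, 0.25)])
    def test_monte_carlo_recovers_elicitation_rate(self, age, p):
        profile = AvatarProfile("mc", age=age, gender="girl", abused=True)
        pack = build_scenario_pack(profile, seed=0)
        rng = np.random.default_rng(99)
        n = 10_000
        hits = 0
        for _ in range(n):
            m = pack.fresh_memory()  # state reset between trials
            if draw_answer_kind(QuestionType.INVITATION_BROAD, profile, m, rng) == "relevant":
                hits += 1
        rate = hits / n
        # 95% binomial CI half-width at p, n=10k
        half = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < half + 1e-12


class TestRespond:
    def test_neutral_plays_lowest_numbered_unplayed_topic_response(self, pack4):
        m = pack4.fresh_memory()
        m.topic_pointers["dad"] = 1  # response #1 already played
        profile = pack4.profile

        # force the neutral branch: u in [p, 2p)
        class FakeRng:
            def random(self):
                return profile.p_elicit + 1e-6

            def integers(self, *a, **k):
                return 0

        q = _cq(QuestionType.INVITATION_FOCUS, "Tell me about your dad", topics=["dad"])
        resp = respond(q, profile, m, FakeRng())
        assert resp.detail_kind == "neutral"
        assert resp.text == m.topic_responses["dad"][1]
        assert m.topic_pointers["dad"] == 2

    def test_incorrect_yes_logged_for_suggestive_to_non_abused(self, pack6):
        m = pack6.fresh_memory()

        class FakeRng:
            def random(self):
                return 0.0  # force incorrect branch

            def integers(self, *a, **k):
                return 0

        q = _cq(QuestionType.SPECIFIC_SUGGESTIVE, "Did your dad hurt you?")
        resp = respond(q, pack6.profile, m, FakeRng())
        assert resp.text == "Yes."
        assert resp.detail_kind == "incorrect"
        assert len(m.incorrect_log) == 1

    def test_repetition_flip_to_yes_is_incorrect(self, pack6):
        m = pack6.fresh_memory()
        m.last_response = "I don't know."

        class FlipRng:
            def random(self):
                return 0.0  # below yes_flip_probability

            def integers(self, *a, **k):
                return 0

        q = _cq(QuestionType.REPETITION, "Did your dad hurt you?")
        resp = respond(q, pack6.profile, m, FlipRng())
        assert resp.text == "Yes."
        assert resp.detail_kind == "incorrect"
        assert len(m.incorrect_log) == 1

    def test_repetition_without_flip_repeats_prior_answer(self, pack6):
        m = pack6.fresh_memory()
        m.last_response = "I don't know."

        class NoFlipRng:
            def random(self):
                return 0.99

            def integers(self, *a, **k):
                return 0

        q = _cq(QuestionType.REPETITION, "Did your dad hurt you?")
        resp = respond(q, pack6.profile, m, NoFlipRng())
        assert resp.text == "I don't know."
        assert resp.detail_kind == "none"

    def test_same_question_flips_at_most_once(self, pack6):
        m = pack6.fresh_memory()
        m.last_response = "No."

        class FlipRng:
            def random(self):
                return 0.0

            def integers(self, *a, **k):
                return 0

        q = _cq(QuestionType.REPETITION, "Did your dad hurt you?")
        r1 = respond(q, pack6.profile, m, FlipRng())
        r2 = respond(q, pack6.profile, m, FlipRng())
        assert r1.detail_kind == "incorrect"
        assert r2.detail_kind == "none"  # no second flip for the same text
        assert len(m.incorrect_log) == 1

    def test_greeting_gets_pleasantry(self, pack4, rng):
        resp = respond(_cq(GREETING, "Hello"), pack4.profile, pack4.fresh_memory(), rng)
        assert resp.detail_kind == "none"
        assert resp.text

    def test_incorrect_log_matches_incorrect_responses(self, pack4, rng):
        m = pack4.fresh_memory()
        n_incorrect = 0
        for _ in range(200):
            q = _cq(QuestionType.OPTION_POSING, "Did you go to the pool?")
            r = respond(q, pack4.profile, m, rng)
            n_incorrect += r.detail_kind == "incorrect"
        assert len(m.incorrect_log) == n_incorrect

    def test_determinism_under_fixed_seed(self, pack4):
        qs = [
            _cq(QuestionType.INVITATION_BROAD, "Tell me everything"),
            _cq(QuestionType.OPTION_POSING, "Did you go there?"),
            _cq(QuestionType.INVITATION_FOCUS, "Tell me about your dad", topics=["dad"]),
        ] * 10
        out = []
        for _ in range(2):
            m = pack4.fresh_memory()
            rng = np.random.default_rng(77)
            out.append([respond(q, pack4.profile, m, rng) for q in qs])
        assert out[0] == out[1]

    def test_relevant_subsequence_is_prefix_of_detail_order(self, pack4, rng):
        m = pack4.fresh_memory()
        got = []
        for _ in range(400):
            r = respond(_cq(QuestionType.INVITATION_BROAD, "Tell me more"), pack4.profile, m, rng)
            if r.detail_kind == "relevant":
                got.append(r.text)
        assert got == m.relevant_details[: len(got)]


class TestScenarioPacks:
    def test_yaml_round_trip(self, pack4, tmp_path):
        path = tmp_path / "pack.yaml"
        pack4.to_yaml(str(path))
        loaded = ScenarioPack.from_yaml(str(path))
        assert loaded.profile == pack4.profile
        assert loaded.memory_template.relevant_details == pack4.memory_template.relevant_details
        assert loaded.memory_template.topic_responses == pack4.memory_template.topic_responses

    def test_malformed_pack_rejected(self, pack4, tmp_path):
        path = tmp_path / "bad.yaml"
        pack4.to_yaml(str(path))
        text = path.read_text().replace("conclusive: true", "conclusive: false", 1)
        path.write_text(text)
        with pytest.raises(ValueError, match="conclusive"):
            ScenarioPack.from_yaml(str(path))

    def test_default_packs_cover_roster(self):
        packs = build_default_packs(seed=0)
        assert len(packs) == 16
        for pack in packs:
            assert len(pack.memory_template.relevant_details) == 9

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            AvatarProfile("x", age=5, gender="girl", abused=False)
        with pytest.raises(ValueError):
            AvatarProfile("x", age=4, gender="other", abused=False)

    def test_conclusive_response_invariant(self):
        with pytest.raises(ValueError):
            AvatarResponse("text", "neutral", conclusive=True)
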