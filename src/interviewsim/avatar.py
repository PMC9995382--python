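"""Probabilistic child-avatar answer selection.

Each avatar is a scripted child witness with a fixed memory of nine
relevant details (the last four jointly conclusive about whether abuse
occurred), topic-keyed lists of neutral responses played in order, and
predefined response probabilities conditioned on question type and age:

* A recommended question elicits a relevant detail with probability 0.20
  (age 4) or 0.25 (age 6), a neutral detail with the same probability,
  and otherwise a non-committal filler — one categorical draw per
  question, because exactly one answer is played per turn.
* A not-recommended question elicits an *incorrect* detail (an answer
  contradicting the avatar's scripted information) with a per-type
  probability, default 0.25.
* Repeating the immediately preceding question can flip a previous
  non-affirmative answer to "Yes" with a predetermined probability;
  the flipped yes is logged as an incorrect detail.

Relevant and neutral details are only ever given for recommended
questions, mirroring how open prompts tap recall memory while closed and
suggestive prompts breed error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .taxonomy import GREETING, Category, QuestionType, category_of

#: Topic id credited when the avatar first reveals a case-relevant detail;
#: suggestive keywords link to it so the override relaxes after disclosure.
INCIDENT_TOPIC = "incident"

DEFAULT_YES_FLIP_PROBABILITY = 0.30
DEFAULT_INCORRECT_PROBABILITY = 0.25

GENERIC_FILLERS = (
    "I don't know.",
    "I don't remember.",
    "Hmm...",
    "Maybe.",
)

GREETING_REPLIES = (
    "Hello.",
    "Hi.",
    "Okay.",
)


@dataclass(frozen=True)
class AvatarProfile:
    """Static avatar features: age, gender, and ground-truth abuse status."""

    avatar_id: str
    age: int  # 4 or 6
    gender: str  # "girl" or "boy"
    abused: bool
    reserved_for_modeling: bool = False

    def __post_init__(self) -> None:
        if self.age not in (4, 6):
            raise ValueError("avatar age must be 4 or 6")
        if self.gender not in ("girl", "boy"):
            raise ValueError("avatar gender must be 'girl' or 'boy'")

    @property
    def p_elicit(self) -> float:
        """Per-question probability of a relevant (and of a neutral) detail."""
        return 0.20 if self.age == 4 else 0.25


@dataclass
class AvatarMemory:
    """Mutable avatar state: detail stock, play pointers, and error log."""

    relevant_details: list[str]
    topic_responses: dict[str, list[str]] = field(default_factory=dict)
    yes_flip_probability: float = DEFAULT_YES_FLIP_PROBABILITY
    incorrect_probability: float | dict[str, float] = DEFAULT_INCORRECT_PROBABILITY
    next_relevant_index: int = 0
    topic_pointers: dict[str, int] = field(default_factory=dict)
    incorrect_log: list[str] = field(default_factory=list)
    flipped_questions: set[str] = field(default_factory=set)
    last_response: str | None = None

    N_RELEVANT = 9
    N_CONCLUSIVE = 4

    def __post_init__(self) -> None:
        if len(self.relevant_details) != self.N_RELEVANT:
            raise ValueError(
                f"an avatar holds exactly {self.N_RELEVANT} relevant details, "
                f"got {len(self.relevant_details)}"
            )

    def is_conclusive(self, index: int) -> bool:
        """The last four relevant details carry the conclusive information."""
        return index >= self.N_RELEVANT - self.N_CONCLUSIVE

    @property
    def exhausted(self) -> bool:
        return self.next_relevant_index >= self.N_RELEVANT

    def emit_relevant(self) -> tuple[str, bool]:
        """Next relevant detail in fixed order; each emitted at most once."""
        if self.exhausted:
            raise RuntimeError("all relevant details already emitted")
        i = self.next_relevant_index
        self.next_relevant_index += 1
        return self.relevant_details[i], self.is_conclusive(i)

    def next_topic_response(self, topics: list[str]) -> str | None:
        """Lowest-numbered unplayed response among the tagged topics."""
        for topic in topics:
            responses = self.topic_responses.get(topic, [])
            ptr = self.topic_pointers.get(topic, 0)
            if ptr < len(responses):
                self.topic_pointers[topic] = ptr + 1
                return responses[ptr]
        return None

    def p_incorrect(self, qtype: QuestionType) -> float:
        if isinstance(self.incorrect_probability, dict):
            return self.incorrect_probability.get(
                qtype.value, DEFAULT_INCORRECT_PROBABILITY
            )
        return self.incorrect_probability


@dataclass(frozen=True)
class AvatarResponse:
    text: str
    detail_kind: str  # relevant | neutral | incorrect | none
    conclusive: bool = False

    def __post_init__(self) -> None:
        if self.conclusive and self.detail_kind != "relevant":
            raise ValueError("only relevant details can be conclusive")


# --------------------------------------------------------------------- roster

def build_roster(seed: int = 0) -> list[AvatarProfile]:
    """The 16-avatar roster: 2 per age x gender x abuse-status pattern.

    Two avatars are reserved for the modeling intervention (a 4-year-old
    non-abused boy and a 6-year-old abused girl), leaving 14 available
    for simulated interviews. The seed shuffles only id assignment.
    """
    patterns = [
        (age, gender, abused)
        for age in (4, 6)
        for gender in ("girl", "boy")
        for abused in (True, False)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patterns) * 2)
    roster: list[AvatarProfile] = []
    reserved_done = {(4, "boy", False): False, (6, "girl", True): False}
    k = 0
    for age, gender, abused in patterns:
        for _ in range(2):
            pattern = (age, gender, abused)
            reserve = pattern in reserved_done and not reserved_done[pattern]
            if reserve:
                reserved_done[pattern] = True
            roster.append(
                AvatarProfile(
                    avatar_id=f"avatar_{order[k]:02d}",
                    age=age,
                    gender=gender,
                    abused=abused,
                    reserved_for_modeling=reserve,
                )
            )
            k += 1
    return roster


# ------------------------------------------------------------- scenario packs

_ABUSED_DETAILS = [
    "I was at {place} with {adult}.",
    "We were alone in the room.",
    "{adult} told me we would play a game.",
    "The door was closed and the TV was loud.",
    "{adult} said it was our secret.",
    "{adult} touched me under my clothes.",
    "It happened more than one time.",
    "{adult} said I would be in trouble if I told.",
    "I was scared and I didn't want to go back.",
]

_NON_ABUSED_DETAILS = [
    "I was at {place} with {adult}.",
    "We were playing in the big room.",
    "{adult} helped me build a tower.",
    "I fell down when we were running.",
    "I got a bruise on my leg from the swing.",
    "{adult} put a plaster on my knee.",
    "Nobody did anything bad to me.",
    "I told my mom about falling down.",
    "I want to go play there again.",
]

_TOPIC_RESPONSES = {
    "dad": [
        "Daddy is kind to me.",
        "Daddy never tells me fairytales.",
        "Sometimes daddy plays with me.",
    ],
    "mom": [
        "Mommy makes my breakfast.",
        "Mommy reads to me at night.",
        "Mommy was at work that day.",
    ],
    "school": [
        "I like drawing at kindergarten.",
        "My teacher is nice.",
        "We sing songs in the morning.",
    ],
    "friend": [
        "My best friend is Kanta.",
        "We play tag outside.",
        "Sometimes we fight about toys.",
    ],
}

_ADULTS = ["my uncle", "the neighbor", "my babysitter", "the coach"]
_PLACES = ["the park", "his house", "the pool", "the club"]


@dataclass
class ScenarioPack:
    """A complete playable avatar: profile, memory script, probabilities."""

    profile: AvatarProfile
    memory_template: AvatarMemory

    def fresh_memory(self) -> AvatarMemory:
        """A reset copy of the scripted memory (pointers at zero)."""
        m = self.memory_template
        return AvatarMemory(
            relevant_details=list(m.relevant_details),
            topic_responses={t: list(r) for t, r in m.topic_responses.items()},
            yes_flip_probability=m.yes_flip_probability,
            incorrect_probability=(
                dict(m.incorrect_probability)
                if isinstance(m.incorrect_probability, dict)
                else m.incorrect_probability
            ),
        )

    def to_yaml(self, path: str) -> None:
        m = self.memory_template
        raw = {
            "profile": {
                "avatar_id": self.profile.avatar_id,
                "age": self.profile.age,
                "gender": self.profile.gender,
                "abused": self.profile.abused,
                "reserved_for_modeling": self.profile.reserved_for_modeling,
            },
            "relevant_details": [
                {"text": d, "conclusive": m.is_conclusive(i)}
                for i, d in enumerate(m.relevant_details)
            ],
            "topic_responses": {t: list(r) for t, r in m.topic_responses.items()},
            "yes_flip_probability": m.yes_flip_probability,
            "incorrect_probability": m.incorrect_probability,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioPack":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        try:
            profile = AvatarProfile(**raw["profile"])
            details = [d["text"] for d in raw["relevant_details"]]
            memory = AvatarMemory(
                relevant_details=details,
                topic_responses={
                    t: list(r) for t, r in raw.get("topic_responses", {}).items()
                },
                yes_flip_probability=raw.get(
                    "yes_flip_probability", DEFAULT_YES_FLIP_PROBABILITY
                ),
                incorrect_probability=raw.get(
                    "incorrect_probability", DEFAULT_INCORRECT_PROBABILITY
                ),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed scenario pack {path}: {exc}") from exc
        flags = [d.get("conclusive", False) for d in raw["relevant_details"]]
        if flags != [memory.is_conclusive(i) for i in range(len(flags))]:
            raise ValueError(
                f"scenario pack {path}: conclusive flags must mark exactly "
                "the last four relevant details"
            )
        return cls(profile=profile, memory_template=memory)


def build_scenario_pack(profile: AvatarProfile, seed: int = 0) -> ScenarioPack:
    """Instantiate the bundled synthetic scenario script for a profile."""
    rng = np.random.default_rng(seed + profile.age * 131 + hash(profile.avatar_id) % 1000)
    adult = _ADULTS[int(rng.integers(len(_ADULTS)))]
    place = _PLACES[int(rng.integers(len(_PLACES)))]
    bank = _ABUSED_DETAILS if profile.abused else _NON_ABUSED_DETAILS
    details = [d.format(adult=adult, place=place) for d in bank]
    memory = AvatarMemory(
        relevant_details=details,
        topic_responses={t: list(r) for t, r in _TOPIC_RESPONSES.items()},
    )
    return ScenarioPack(profile=profile, memory_template=memory)


def build_default_packs(seed: int = 0) -> list[ScenarioPack]:
    return [build_scenario_pack(p, seed) for p in build_roster(seed)]


# ------------------------------------------------------------ answer selection

def draw_answer_kind(
    qtype: QuestionType | str,
    profile: AvatarProfile,
    state: AvatarMemory,
    rng: np.random.Generator,
) -> str:
    """One categorical draw deciding the kind of detail, if any.

    Recommended question: relevant with p_elicit, neutral with p_elicit,
    else none; a relevant draw falls through to neutral once all nine
    details are spent. Not-recommended question: incorrect with the
    per-type probability, else none. Greetings never yield details.
    """
    if qtype == GREETING:
        return "none"
    qt = QuestionType(qtype)
    if category_of(qt) is Category.RECOMMENDED:
        u = rng.random()
        p = profile.p_elicit
        if u < p:
            return "relevant" if not state.exhausted else "neutral"
        if u < 2 * p:
            return "neutral"
        return "none"
    if rng.random() < state.p_incorrect(qt):
        return "incorrect"
    return "none"


def respond(
    q,  # ClassifiedQuestion
    profile: AvatarProfile,
    state: AvatarMemory,
    rng: np.random.Generator,
) -> AvatarResponse:
    """Select and play one answer; mutates ``state`` (pointers, logs, cache)."""
    if q.is_greeting:
        reply = GREETING_REPLIES[int(rng.integers(len(GREETING_REPLIES)))]
        response = AvatarResponse(reply, "none")
    elif q.qtype is QuestionType.REPETITION:
        response = _respond_repetition(q, state, rng)
    else:
        kind = draw_answer_kind(q.qtype, profile, state, rng)
        if kind == "relevant":
            text, conclusive = state.emit_relevant()
            response = AvatarResponse(text, "relevant", conclusive)
        elif kind == "neutral":
            text = state.next_topic_response(q.topics)
            if text is None:
                # topic lists exhausted or question untagged: generic filler
                filler = GENERIC_FILLERS[int(rng.integers(len(GENERIC_FILLERS)))]
                response = AvatarResponse(filler, "none")
            else:
                response = AvatarResponse(text, "neutral")
        elif kind == "incorrect":
            response = AvatarResponse("Yes.", "incorrect")
            state.incorrect_log.append(f"{q.text} -> Yes.")
        else:
            filler = GENERIC_FILLERS[int(rng.integers(len(GENERIC_FILLERS)))]
            response = AvatarResponse(filler, "none")
    state.last_response = response.text
    return response


def _respond_repetition(q, state: AvatarMemory, rng: np.random.Generator) -> AvatarResponse:
    """Repeated question: possible one-time flip of the previous answer to yes.

    The flip contradicts the answer just given, so it is logged as an
    incorrect detail. A given question text can flip at most once;
    otherwise the avatar repeats its previous non-answer.
    """
    can_flip = (
        q.text not in state.flipped_questions
        and state.last_response is not None
        and state.last_response != "Yes."
    )
    if can_flip and rng.random() < state.yes_flip_probability:
        state.flipped_questions.add(q.text)
        state.incorrect_log.append(f"{q.text} -> Yes. (flipped)")
        return AvatarResponse("Yes.", "incorrect")
    repeat = state.last_response or "I don't know."
    return AvatarResponse(repeat, "none")


def case_ground_truth(profile: AvatarProfile, memory: AvatarMemory) -> dict:
    """Case outcome for feedback: abuse present/absent + conclusive details."""
    conclusive = [
        d
        for i, d in enumerate(memory.relevant_details)
        if memory.is_conclusive(i)
    ]
    return {
        "avatar_id": profile.avatar_id,
        "abuse": "present" if profile.abused else "absent",
        "conclusive_details": conclusive,
    }
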