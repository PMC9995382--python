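"""Training interventions delivered between interviews.

Two interventions are supported. *Feedback* combines the ground-truth
case outcome with comments on up to two recommended and two
not-recommended questions sampled uniformly from the completed
interview's transcript. *Modeling* presents a set of learning points
followed by four annotated example interviews covering the good/bad x
abused/non-abused design, each framed by its background scenario and
case outcome — instruction by observing exemplars of target behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .avatar import ScenarioPack, case_ground_truth
from .rules import ClassifiedQuestion
from .session import Transcript
from .taxonomy import Category, QuestionType

#: Per-type comment templates; {text} is the interviewer's own question.
PRAISE_TEMPLATES: dict[QuestionType, str] = {
    QuestionType.INVITATION_BROAD: (
        'You asked "{text}" — an open invitation like this lets the child '
        "tell the story in their own words and draws on recall memory."
    ),
    QuestionType.INVITATION_FOCUS: (
        'You asked "{text}" — focusing an open invitation on a topic the '
        "interview needs is a strong way to gather detail without leading."
    ),
    QuestionType.FACILITATOR: (
        'Saying "{text}" encouraged the child to keep talking without '
        "steering the content. Well done."
    ),
    QuestionType.DIRECTIVE: (
        'You asked "{text}" — following up on something the child already '
        "mentioned is a sound way to get specifics."
    ),
    QuestionType.CLARIFICATION: (
        'You asked "{text}" — checking what the child actually said avoids '
        "misunderstandings entering the record."
    ),
}

CRITIQUE_TEMPLATES: dict[QuestionType, str] = {
    QuestionType.OPTION_POSING: (
        'You asked "{text}". This yes/no question introduces content the '
        "child had not mentioned; try an open prompt such as "
        '"Tell me more about that."'
    ),
    QuestionType.SPECIFIC_SUGGESTIVE: (
        'You asked "{text}". The question assumes details the child never '
        "reported and signals the expected answer; children often comply. "
        "Let the child's own account lead."
    ),
    QuestionType.UNSPECIFIC_SUGGESTIVE: (
        'You asked "{text}". Pressing the child that something must have '
        "happened invites inaccurate reports; invite narrative instead."
    ),
    QuestionType.REPETITION: (
        'You asked "{text}" again. Repeating a question signals the first '
        "answer was wrong, and children may switch to an inaccurate answer."
    ),
    QuestionType.INAPPROPRIATE_UTTERANCE: (
        'You asked "{text}". Compound, abstract, or time-reasoning '
        "questions exceed young children's capacities; ask one simple "
        "thing at a time."
    ),
    QuestionType.MULTIPLE_CHOICE: (
        'You asked "{text}". Forced choices push children to pick an '
        "option even when no option is right; prefer an open question."
    ),
}

DEFAULT_LEARNING_POINTS = (
    "Open, non-suggestive prompts (invitations, facilitators) elicit the "
    "most accurate information from children.",
    "Closed and suggestive questions can create incorrect details: "
    "children tend to comply with what a question implies.",
    "Do not repeat a question the child has already answered — repetition "
    "pressures children into changing accurate answers.",
    "Follow up on what the child has said (directives, clarifications) "
    "rather than introducing new content yourself.",
    "Keep questions short, concrete, and one at a time.",
)


@dataclass(frozen=True)
class FeedbackItem:
    question: ClassifiedQuestion
    comment: str


@dataclass
class FeedbackReport:
    case_outcome: dict
    praised: list[FeedbackItem]
    critiqued: list[FeedbackItem]
    shortfall_note: str | None = None

    def to_markdown(self) -> str:
        lines = ["# Interview feedback", "", "## Case outcome", ""]
        lines.append(f"Abuse was **{self.case_outcome['abuse']}** in this case.")
        lines.append("The conclusive details were:")
        lines += [f"- {d}" for d in self.case_outcome["conclusive_details"]]
        lines += ["", "## Questions that worked well", ""]
        lines += [f"- {item.comment}" for item in self.praised] or ["- (none available)"]
        lines += ["", "## Questions to reconsider", ""]
        lines += [f"- {item.comment}" for item in self.critiqued] or ["- (none available)"]
        if self.shortfall_note:
            lines += ["", f"*{self.shortfall_note}*"]
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "case_outcome": self.case_outcome,
            "praised": [
                {"question": i.question.text, "qtype": _qtype_value(i.question), "comment": i.comment}
                for i in self.praised
            ],
            "critiqued": [
                {"question": i.question.text, "qtype": _qtype_value(i.question), "comment": i.comment}
                for i in self.critiqued
            ],
            "shortfall_note": self.shortfall_note,
        }


def _qtype_value(cq: ClassifiedQuestion) -> str:
    return cq.qtype.value if isinstance(cq.qtype, QuestionType) else str(cq.qtype)


def generate_feedback(
    transcript: Transcript, pack: ScenarioPack, rng: np.random.Generator
) -> FeedbackReport:
    """Outcome feedback plus 2 + 2 sampled question comments.

    Samples uniformly without replacement up to two recommended and two
    not-recommended questions from the transcript's substantive turns;
    when a category has fewer than two, all of it is used and the report
    carries a shortfall note. Reproducible under a seeded generator.
    """
    substantive = [t.classified for t in transcript.turns if not t.classified.is_greeting]
    if not substantive:
        raise ValueError("cannot generate feedback for an empty transcript")
    rec = [q for q in substantive if q.category is Category.RECOMMENDED]
    notrec = [q for q in substantive if q.category is Category.NOT_RECOMMENDED]

    def sample(pool: list[ClassifiedQuestion], k: int) -> list[ClassifiedQuestion]:
        if len(pool) <= k:
            return list(pool)
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(idx)]

    praised = [
        FeedbackItem(q, PRAISE_TEMPLATES[q.qtype].format(text=q.text))
        for q in sample(rec, 2)
    ]
    critiqued = [
        FeedbackItem(q, CRITIQUE_TEMPLATES[q.qtype].format(text=q.text))
        for q in sample(notrec, 2)
    ]
    notes = []
    if len(praised) < 2:
        notes.append(f"only {len(praised)} recommended question(s) were available")
    if len(critiqued) < 2:
        notes.append(f"only {len(critiqued)} not-recommended question(s) were available")
    return FeedbackReport(
        case_outcome=case_ground_truth(pack.profile, pack.memory_template),
        praised=praised,
        critiqued=critiqued,
        shortfall_note="; ".join(notes) if notes else None,
    )


# ------------------------------------------------------------------ modeling

#: The 2x2 design every modeling package must cover.
MODELING_CELLS = (
    ("good", "abused"),
    ("good", "non_abused"),
    ("bad", "abused"),
    ("bad", "non_abused"),
)


@dataclass(frozen=True)
class ModelingExample:
    """One annotated exemplar interview (text stands in for video)."""

    quality: str  # "good" | "bad"
    case: str  # "abused" | "non_abused"
    scenario: str  # background read before the example
    transcript_text: str  # the annotated example interview
    outcome: str  # case outcome read after

    def __post_init__(self) -> None:
        if self.quality not in ("good", "bad"):
            raise ValueError("quality must be 'good' or 'bad'")
        if self.case not in ("abused", "non_abused"):
            raise ValueError("case must be 'abused' or 'non_abused'")


@dataclass
class ModelingPackage:
    learning_points: tuple[str, ...] = DEFAULT_LEARNING_POINTS
    examples: list[ModelingExample] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelingPackage":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            learning_points=tuple(raw.get("learning_points", DEFAULT_LEARNING_POINTS)),
            examples=[ModelingExample(**e) for e in raw.get("examples", [])],
        )


class ModelingConfigError(ValueError):
    pass


def deliver_modeling(package: ModelingPackage) -> str:
    """Render the modeling intervention as an ordered presentation script.

    Learning points first, then for each of the four examples: background
    scenario, the example interview, the case outcome. Pure formatting —
    an incomplete 2x2 example set is a configuration error naming the
    missing cell.
    """
    have = {(e.quality, e.case) for e in package.examples}
    missing = [cell for cell in MODELING_CELLS if cell not in have]
    if missing:
        raise ModelingConfigError(
            "modeling package is missing example(s): "
            + ", ".join(f"{q}/{c}" for q, c in missing)
        )
    if len(package.examples) != 4:
        raise ModelingConfigError("modeling package must contain exactly 4 examples")

    lines = ["# Learning points", ""]
    lines += [f"{i + 1}. {p}" for i, p in enumerate(package.learning_points)]
    by_cell = {(e.quality, e.case): e for e in package.examples}
    for quality, case in MODELING_CELLS:
        e = by_cell[(quality, case)]
        title = f"{quality} interview, {case.replace('_', '-')} case"
        lines += ["", f"# Example: {title}", "", "## Background scenario", "", e.scenario]
        lines += ["", "## Example interview", "", e.transcript_text]
        lines += ["", "## Case outcome", "", e.outcome]
    return "\n".join(lines)


def default_modeling_package() -> ModelingPackage:
    """The bundled synthetic modeling package (text exemplars)."""
    good_abused = (
        "Interviewer: Tell me everything that happened from the beginning "
        "to the end.\nChild: I was at the pool with my uncle... [the child "
        "narrates; the interviewer follows up with open prompts and the "
        "conclusive details emerge one by one]"
    )
    bad_abused = (
        "Interviewer: Did your dad do something bad to you?\nChild: ...\n"
        "Interviewer: Did your dad do something bad to you?\nChild: Yes.\n"
        "[the repeated suggestive question produces an incorrect detail "
        "and the real account never surfaces]"
    )
    good_non = good_abused.replace("my uncle", "my babysitter")
    bad_non = bad_abused
    scen_a = (
        "A kindergarten teacher noticed the child flinching from contact "
        "and reported a concern. You will interview the child."
    )
    scen_n = (
        "The child came home with a bruise after an afternoon at a "
        "neighbor's house. The parents asked for an interview."
    )
    return ModelingPackage(
        examples=[
            ModelingExample("good", "abused", scen_a, good_abused,
                            "Abuse was present; the open questioning surfaced all conclusive details."),
            ModelingExample("good", "non_abused", scen_n, good_non,
                            "No abuse had occurred; the open questioning established the innocent explanation."),
            ModelingExample("bad", "abused", scen_a, bad_abused,
                            "Abuse was present, but the suggestive questioning produced unreliable details."),
            ModelingExample("bad", "non_abused", scen_n, bad_non,
                            "No abuse had occurred, yet the questioning created a false affirmation."),
        ]
    )
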