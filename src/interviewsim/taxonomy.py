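"""Question-type taxonomy for investigative interviews with children.

Eleven substantive question types, partitioned into *recommended*
(open-ended, non-suggestive prompts that promote recall memory) and
*not recommended* (closed, suggestive, repeated, or developmentally
inappropriate prompts that risk eliciting inaccurate answers).

Greetings and rapport utterances ("Hello", "How old are you") are not
part of the taxonomy: they are handled by an if-then rule layer and carry
the pseudo-label :data:`GREETING`, excluded from quality counts and
agreement statistics.
"""

from __future__ import annotations

import enum
import json
from typing import Iterable


class TaxonomyError(KeyError):
    """Raised when a label is not one of the 11 question types."""


class Category(str, enum.Enum):
    """The two-way quality partition of question types."""

    RECOMMENDED = "recommended"
    NOT_RECOMMENDED = "not_recommended"


class QuestionType(str, enum.Enum):
    """The 11 question types, with stable integer codes in table order."""

    INVITATION_BROAD = "invitation_broad"
    INVITATION_FOCUS = "invitation_focus"
    FACILITATOR = "facilitator"
    DIRECTIVE = "directive"
    CLARIFICATION = "clarification"
    OPTION_POSING = "option_posing"
    SPECIFIC_SUGGESTIVE = "specific_suggestive"
    UNSPECIFIC_SUGGESTIVE = "unspecific_suggestive"
    REPETITION = "repetition"
    INAPPROPRIATE_UTTERANCE = "inappropriate_utterance"
    MULTIPLE_CHOICE = "multiple_choice"

    @property
    def code(self) -> int:
        """Stable integer code (0-10) used for model label encoding."""
        return _CODES[self]

    @property
    def category(self) -> Category:
        return category_of(self)

    @property
    def description(self) -> str:
        return _DESCRIPTIONS[self]


#: Pseudo-label for rapport utterances handled by the rule layer.
GREETING = "greeting"

_ORDER = list(QuestionType)
_CODES = {qt: i for i, qt in enumerate(_ORDER)}

_RECOMMENDED = frozenset(
    {
        QuestionType.INVITATION_BROAD,
        QuestionType.INVITATION_FOCUS,
        QuestionType.FACILITATOR,
        QuestionType.DIRECTIVE,
        QuestionType.CLARIFICATION,
    }
)

_DESCRIPTIONS = {
    QuestionType.INVITATION_BROAD: (
        "Open-ended, non-suggestive question eliciting free narrative."
    ),
    QuestionType.INVITATION_FOCUS: (
        "Open-ended, non-suggestive question eliciting narrative about a "
        "focused topic."
    ),
    QuestionType.FACILITATOR: (
        "Non-suggestive prompt encouraging further narrative about content "
        "already mentioned."
    ),
    QuestionType.DIRECTIVE: (
        "Question focusing attention on content the child already mentioned, "
        "for further explanation."
    ),
    QuestionType.CLARIFICATION: "Attempt to clarify what the child has said.",
    QuestionType.OPTION_POSING: (
        "Closed question focusing attention on content not yet mentioned, "
        "without implying a specific answer."
    ),
    QuestionType.SPECIFIC_SUGGESTIVE: (
        "Question indicating the expected answer by assuming details the "
        "child has not mentioned."
    ),
    QuestionType.UNSPECIFIC_SUGGESTIVE: (
        "Question indicating the expected answer without assuming specific "
        "unmentioned details."
    ),
    QuestionType.REPETITION: (
        "Asking again what the interviewer has just asked."
    ),
    QuestionType.INAPPROPRIATE_UTTERANCE: (
        "Question unsuited to eliciting correct information from children "
        "(multiple details at once, difficult words, unclear grammar, "
        "temporal reasoning, or fantasy prompts)."
    ),
    QuestionType.MULTIPLE_CHOICE: (
        "Question forcing the child to choose among offered options."
    ),
}


def coerce_qtype(label: "QuestionType | str") -> QuestionType:
    """Return the :class:`QuestionType` for a label, or raise TaxonomyError."""
    if isinstance(label, QuestionType):
        return label
    try:
        return QuestionType(label)
    except ValueError:
        raise TaxonomyError(f"unknown question type: {label!r}") from None


def category_of(qtype: "QuestionType | str") -> Category:
    """Map a question type to its recommended / not-recommended category.

    Total over the 11 types; any other label raises :class:`TaxonomyError`.
    """
    qt = coerce_qtype(qtype)
    return Category.RECOMMENDED if qt in _RECOMMENDED else Category.NOT_RECOMMENDED


def qtype_from_code(code: int) -> QuestionType:
    """Inverse of ``QuestionType.code``."""
    try:
        return _ORDER[code]
    except (IndexError, TypeError):
        raise TaxonomyError(f"unknown question-type code: {code!r}") from None


def label_codes() -> dict[str, int]:
    """Label-value → integer code map used by the classifier."""
    return {qt.value: qt.code for qt in _ORDER}


def taxonomy_records() -> list[dict]:
    """The taxonomy as plain records (label, code, category, description)."""
    return [
        {
            "label": qt.value,
            "code": qt.code,
            "category": qt.category.value,
            "description": qt.description,
        }
        for qt in _ORDER
    ]


def dump_taxonomy_json() -> str:
    return json.dumps(taxonomy_records(), indent=2)


def load_taxonomy_json(text: str) -> list[dict]:
    """Re-read a dumped taxonomy and validate it against the package's own."""
    records = json.loads(text)
    if records != taxonomy_records():
        raise TaxonomyError("serialized taxonomy does not match the package taxonomy")
    return records


def load_bundled_taxonomy() -> list[dict]:
    """The taxonomy resource shipped with the package, validated on read."""
    from importlib import resources

    text = resources.files("interviewsim").joinpath("data/taxonomy.json").read_text()
    return load_taxonomy_json(text)


def recommended_types() -> tuple[QuestionType, ...]:
    return tuple(qt for qt in _ORDER if qt in _RECOMMENDED)


def not_recommended_types() -> tuple[QuestionType, ...]:
    return tuple(qt for qt in _ORDER if qt not in _RECOMMENDED)


def validate_labels(labels: Iterable[str]) -> None:
    """Raise TaxonomyError if any label is outside the 11-type space."""
    for lab in labels:
        coerce_qtype(lab)
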