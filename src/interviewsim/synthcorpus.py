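"""Synthetic labeled question corpora for training and testing.

The original training corpus (thousands of human-coded interviewer
questions) is not publicly deposited, so this module generates labeled
stand-in corpora with the statistical structure the pipeline needs:
eleven classes with configurable imbalance, template banks seeded by the
published example utterances, shared slot lexicons (names, places,
actions) so no class is separable by a trivial artifact token,
suggestive-keyword questions aligned with the rule layer's lexicon, and
repetition items emitted as adjacent near-duplicate pairs. No linguistic
realism is claimed; the corpus exists so that the full system trains,
runs, and is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .avatar import INCIDENT_TOPIC
from .rules import RuleConfig, SuggestiveKeyword
from .taxonomy import GREETING, Category, QuestionType, category_of

# Slot lexicons are shared across every class on purpose.
_SLOTS = {
    "name": ["Kanta", "Miura", "Yuki", "Hana"],
    "name2": ["Taro", "Aya", "Ken", "Mio"],
    "person": ["dad", "mom", "uncle", "teacher"],
    "person2": ["grandma", "brother", "sister", "coach"],
    "place": ["park", "school", "pool", "house"],
    "place2": ["garden", "club", "beach", "shop"],
    "object": ["ball", "toy", "book", "game"],
}

#: Keywords betraying an assumed, undisclosed harmful experience; each is
#: linked to the incident topic so disclosure relaxes the override.
SUGGESTIVE_LEXICON = ("hurt", "bad", "secret", "touched", "hiding")

TEMPLATE_BANK: dict[QuestionType, list[str]] = {
    QuestionType.INVITATION_BROAD: [
        "Tell me everything that happened from the beginning to the end",
        "Tell me everything that happened that day",
        "Tell me what happened",
        "Start from the beginning and tell me everything",
        "Tell me all about what happened, every little thing",
    ],
    QuestionType.INVITATION_FOCUS: [
        "Tell me about your family",
        "Tell me about your {person}",
        "Tell me more about the {place}",
        "Tell me about that day at the {place}",
        "Tell me about {name}",
    ],
    QuestionType.FACILITATOR: [
        "Continue",
        "Go ahead",
        "Ok",
        "And then",
        "Uh huh, tell me more",
    ],
    QuestionType.DIRECTIVE: [
        "Where did you go with your {person}?",
        "What game did you play?",
        "Who was with you at the {place}?",
        "What did you do at the {place} you told me about?",
        "What happened after you went to the {place}?",
    ],
    QuestionType.CLARIFICATION: [
        "What did you say?",
        "I did not hear you well, so tell me again",
        "Can you say that again?",
        "What do you mean by that?",
        "Sorry, say that one more time please",
    ],
    QuestionType.OPTION_POSING: [
        "Do you play with {person}?",
        "Did you go to the {place}?",
        "Was {name} there too?",
        "Do you like going to the {place}?",
        "Did you see the {object} there?",
    ],
    QuestionType.SPECIFIC_SUGGESTIVE: [
        "Did your {person} do something bad to you?",
        "Is your {person} a bad person?",
        "Did your {person} hurt you at the {place}?",
        "Your {person} touched you, didn't he?",
        "He told you to keep it a secret, didn't he?",
    ],
    QuestionType.UNSPECIFIC_SUGGESTIVE: [
        "I know that you have something bad to talk about, tell me!",
        "You can tell me the bad thing that happened",
        "I know someone hurt you, just say it",
        "Everyone knows something bad happened, tell me",
        "There is something you are hiding, tell me now",
    ],
    # placeholder; repetition items are near-duplicates of other rows
    QuestionType.REPETITION: [],
    QuestionType.INAPPROPRIATE_UTTERANCE: [
        "Where were you with your {person}, what were you doing after that?",
        "What is the relationship between {person} and {person2}?",
        "When did your {person} leave the {place}?",
        "If you were your {person}, what would you do?",
        "Regarding the antecedent circumstances, what transpired subsequently?",
    ],
    QuestionType.MULTIPLE_CHOICE: [
        "Did you go practicing football with {name} or {name2}?",
        "Was it the {place} or the {place2}?",
        "Did it happen in the morning or at night?",
        "Was it {name} or your {person} who was there?",
        "Did you walk there or ride a bike?",
    ],
}

GREETING_BANK = [
    "Hello",
    "Hi, nice to meet you",
    "How old are you?",
    "What is your name?",
    "How are you today?",
]


@dataclass
class CorpusSpec:
    """What to generate: class counts, templates, lexicons, and a seed."""

    per_class_counts: dict[QuestionType, int]
    template_bank: dict[QuestionType, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in TEMPLATE_BANK.items()}
    )
    slot_lexicons: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in _SLOTS.items()}
    )
    suggestive_lexicon: tuple[str, ...] = SUGGESTIVE_LEXICON
    repetition_pair_fraction: float = 0.05
    n_greetings: int = 0
    language_mode: str = "latin_word"  # or "cjk_char"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.per_class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if not (0 <= self.repetition_pair_fraction <= 1):
            raise ValueError("repetition_pair_fraction must be in [0, 1]")
        if self.language_mode not in ("latin_word", "cjk_char"):
            raise ValueError("language_mode must be 'latin_word' or 'cjk_char'")


def default_spec(
    language_mode: str = "latin_word",
    base_count: int = 150,
    decay: float = 0.87,
    seed: int = 0,
) -> CorpusSpec:
    """The bundled default: geometric class imbalance in table order.

    Counts decay geometrically across the 11 classes (ratio between the
    largest and smallest class > 3) so that rebalancing is a non-trivial
    part of training, mirroring the existence — not the values — of the
    class imbalance in real question corpora. The repetition-class count
    is tied to ``repetition_pair_fraction`` of the substantive total.
    """
    types = list(QuestionType)
    counts = {qt: max(1, round(base_count * decay**i)) for i, qt in enumerate(types)}
    non_rep = sum(n for qt, n in counts.items() if qt is not QuestionType.REPETITION)
    frac = 0.05
    counts[QuestionType.REPETITION] = max(6, round(frac * non_rep))
    return CorpusSpec(
        per_class_counts=counts,
        repetition_pair_fraction=frac,
        language_mode=language_mode,
        seed=seed,
    )


def balanced_spec(per_class: int = 150, language_mode: str = "latin_word", seed: int = 0) -> CorpusSpec:
    """Equal counts for every class (useful for controlled experiments)."""
    return CorpusSpec(
        per_class_counts={qt: per_class for qt in QuestionType},
        language_mode=language_mode,
        seed=seed,
    )


def _fill(template: str, lexicons: dict[str, list[str]], rng: np.random.Generator) -> str:
    out = template
    for slot, values in lexicons.items():
        while "{" + slot + "}" in out:
            out = out.replace("{" + slot + "}", values[int(rng.integers(len(values)))], 1)
    return out


def _to_cjk_char_mode(text: str) -> str:
    """Whitespace-free rendering that exercises the character-unit pathway."""
    return text.replace(" ", "")


def generate_corpus(spec: CorpusSpec) -> pd.DataFrame:
    """Emit a (text, label) corpus matching the spec's class counts exactly.

    Repetition items appear immediately after a near-duplicate of a row
    from another class, as they would in a live interview; deterministic
    under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[str, str]] = []
    for qt, n in spec.per_class_counts.items():
        if qt is QuestionType.REPETITION or n == 0:
            continue
        bank = spec.template_bank.get(qt, [])
        if not bank:
            raise ValueError(f"no templates for requested class {qt.value}")
        for _ in range(n):
            tmpl = bank[int(rng.integers(len(bank)))]
            rows.append((_fill(tmpl, spec.slot_lexicons, rng), qt.value))
    rng.shuffle(rows)  # type: ignore[arg-type]

    n_rep = spec.per_class_counts.get(QuestionType.REPETITION, 0)
    if n_rep and not rows:
        raise ValueError("repetition items need at least one substantive row")
    out: list[tuple[str, str]] = []
    rep_after = set(rng.choice(len(rows), size=min(n_rep, len(rows)), replace=False)) if rows else set()
    extra = max(0, n_rep - len(rows))
    for i, (text, label) in enumerate(rows):
        out.append((text, label))
        if i in rep_after:
            out.append((_near_duplicate(text, rng), QuestionType.REPETITION.value))
    for _ in range(extra):  # degenerate tiny-corpus case
        text = rows[int(rng.integers(len(rows)))][0]
        out.append((_near_duplicate(text, rng), QuestionType.REPETITION.value))

    for _ in range(spec.n_greetings):
        bank = GREETING_BANK
        out.append((bank[int(rng.integers(len(bank)))], GREETING))

    if spec.language_mode == "cjk_char":
        out = [(_to_cjk_char_mode(t), l) for t, l in out]
    return pd.DataFrame(out, columns=["text", "label"])


def _near_duplicate(text: str, rng: np.random.Generator) -> str:
    """A consecutive re-ask: verbatim or lightly perturbed."""
    u = rng.random()
    if u < 0.5:
        return text
    if u < 0.75:
        return text.rstrip("?!. ") + ", right?"
    return "So, " + text[0].lower() + text[1:]


def write_corpus_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def read_corpus_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["text", "label"]:
        raise ValueError(f"{path}: corpus must have 'text,label' columns")
    return df


def default_rule_config() -> RuleConfig:
    """Rule layer matched to the bundled lexicons and avatar topics."""
    return RuleConfig(
        suggestive_keywords=tuple(
            SuggestiveKeyword(k, INCIDENT_TOPIC) for k in SUGGESTIVE_LEXICON
        ),
        topic_keywords={
            "dad": ("dad", "daddy", "father"),
            "mom": ("mom", "mommy", "mother"),
            "school": ("school", "kindergarten"),
            "friend": ("friend", "friends"),
        },
        jaccard_threshold=0.5,
    )


def interviewer_templates() -> tuple[list[str], list[str]]:
    """(recommended, not-recommended) question banks for scripted interviewers.

    Recommended templates avoid the suggestive lexicon so the override
    does not re-code them; slots are pre-filled with fixed values so the
    banks are constants.
    """
    rng = np.random.default_rng(12345)
    rec: list[str] = []
    notrec: list[str] = []
    for qt, bank in TEMPLATE_BANK.items():
        if qt is QuestionType.REPETITION:
            continue
        filled = [_fill(t, _SLOTS, rng) for t in bank]
        if category_of(qt) is Category.RECOMMENDED:
            rec.extend(filled)
        else:
            notrec.extend(filled)
    return rec, notrec
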