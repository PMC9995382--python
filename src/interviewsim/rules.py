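"""Deterministic rule layer wrapped around the machine-learned classifier.

Four mechanisms supplement the model, applied in a strict precedence
order: (1) greeting if-then rules, (2) repetition detection via the
Jaccard coefficient against the immediately preceding question, (3) the
model prediction itself with a suggestive-keyword override, and (4)
topic-keyword tagging of recommended questions. Precedence is frozen:
greeting > repetition > model (+ override). Repetition precedes the
model because a repeated question is its own question type regardless of
its content.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .featurize import FeaturizerConfig, extract_ngrams, jaccard, normalize
from .taxonomy import GREETING, Category, QuestionType, category_of

#: Rapport/greeting utterances handled before any other mechanism.
DEFAULT_GREETING_PATTERNS = (
    "hello",
    "hi",
    "good morning",
    "good afternoon",
    "how old are you",
    "what is your name",
    "whats your name",
    "nice to meet you",
    "how are you",
    "my name is",
)


@dataclass(frozen=True)
class SuggestiveKeyword:
    """A keyword that betrays an assumed, undisclosed experience.

    ``topic`` optionally names the topic whose prior mention by the avatar
    suppresses the override; an unlinked keyword always triggers it.
    """

    keyword: str
    topic: str | None = None


@dataclass
class RuleConfig:
    greeting_patterns: tuple[str, ...] = DEFAULT_GREETING_PATTERNS
    suggestive_keywords: tuple[SuggestiveKeyword, ...] = ()
    topic_keywords: dict[str, tuple[str, ...]] = field(default_factory=dict)
    jaccard_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.jaccard_threshold <= 1):
            raise ValueError("jaccard_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str) -> "RuleConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kws = tuple(
            SuggestiveKeyword(k["keyword"], k.get("topic"))
            if isinstance(k, dict)
            else SuggestiveKeyword(k)
            for k in raw.get("suggestive_keywords", [])
        )
        return cls(
            greeting_patterns=tuple(raw.get("greetings", DEFAULT_GREETING_PATTERNS)),
            suggestive_keywords=kws,
            topic_keywords={t: tuple(v) for t, v in raw.get("topics", {}).items()},
            jaccard_threshold=raw.get("jaccard_threshold", 0.5),
        )

    def to_yaml(self, path: str) -> None:
        raw = {
            "greetings": list(self.greeting_patterns),
            "suggestive_keywords": [
                {"keyword": k.keyword, "topic": k.topic} for k in self.suggestive_keywords
            ],
            "topics": {t: list(v) for t, v in self.topic_keywords.items()},
            "jaccard_threshold": self.jaccard_threshold,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False, allow_unicode=True)


@dataclass
class DialogueContext:
    """Mutable conversational state the rule layer conditions on."""

    mentioned_topics: set[str] = field(default_factory=set)
    previous_question_features: dict[str, int] | None = None
    turn_index: int = 0

    def advance(self, features: dict[str, int], produced_topics: set[str] = frozenset()) -> None:
        """Record a completed turn: cache its features, note new topics."""
        self.previous_question_features = features
        self.mentioned_topics |= set(produced_topics)
        self.turn_index += 1


@dataclass
class ClassifiedQuestion:
    """One coded utterance: label, category, topic tags, and provenance."""

    text: str
    features: dict[str, int]
    qtype: QuestionType | str  # a QuestionType, or the greeting pseudo-label
    category: Category | None
    topics: list[str] = field(default_factory=list)
    source: str = "model"  # greeting_rule | repetition_rule | model | suggestive_override

    @property
    def is_greeting(self) -> bool:
        return self.qtype == GREETING


_NORM_CFG = FeaturizerConfig(unit="word", n_min=1, n_max=1)


def _norm(text: str) -> str:
    return normalize(text, _NORM_CFG)


def match_greeting(text: str, cfg: RuleConfig) -> bool:
    """True iff the normalized text contains any greeting pattern."""
    norm = _norm(text)
    if not norm:
        return False
    padded = f" {norm} "
    return any(f" {_norm(p)} " in padded for p in cfg.greeting_patterns if _norm(p))


def detect_repetition(
    current: dict[str, int], context: DialogueContext, cfg: RuleConfig
) -> bool:
    """Is this a repetition of the immediately preceding question?

    Presence-only Jaccard similarity against the cached previous features;
    the first question of an interview is never a repetition. Scope is
    only the directly preceding question, not the whole history.
    """
    if context.previous_question_features is None:
        return False
    return jaccard(current, context.previous_question_features) >= cfg.jaccard_threshold


def suggestive_override(
    text: str,
    model_qtype: QuestionType,
    context: DialogueContext,
    cfg: RuleConfig,
) -> QuestionType:
    """Re-code a recommended-looking question that assumes undisclosed harm.

    "Tell me about someone hurting you" resembles a focused invitation,
    but is suggestive when the child has said nothing about a painful
    experience. A not-recommended model label is never changed.
    """
    if category_of(model_qtype) is not Category.RECOMMENDED:
        return model_qtype
    norm = _norm(text)
    for kw in cfg.suggestive_keywords:
        # substring match so "hurt" also catches "hurting"
        if _norm(kw.keyword) in norm:
            if kw.topic is None or kw.topic not in context.mentioned_topics:
                return QuestionType.UNSPECIFIC_SUGGESTIVE
    return model_qtype


def tag_topics(text: str, qtype: QuestionType | str, cfg: RuleConfig) -> list[str]:
    """Topic ids triggered by the text, in config order.

    Only recommended questions are tagged — topic-keyed responses reward
    appropriate questioning; suggestive mentions of the same words do not.
    """
    if qtype == GREETING or category_of(qtype) is not Category.RECOMMENDED:
        return []
    padded = f" {_norm(text)} "
    hits = []
    for topic, triggers in cfg.topic_keywords.items():
        if any(f" {_norm(t)} " in padded for t in triggers):
            hits.append(topic)
    return hits


def classify(
    text: str,
    context: DialogueContext,
    model,
    cfg: RuleConfig,
    featurizer_cfg: FeaturizerConfig | None = None,
) -> ClassifiedQuestion:
    """Code one utterance in conversational context.

    Pathway: greeting rule, then repetition rule, then model prediction
    with the suggestive override, then topic tagging. Pure — the caller
    advances ``context`` afterwards. ``model`` may be None when the rule
    layer alone suffices (greeting/repetition); substantive questions then
    raise.
    """
    fcfg = featurizer_cfg or (model.featurizer_cfg if model is not None else FeaturizerConfig())
    features = extract_ngrams(text, replace(fcfg, vocabulary=None))

    if match_greeting(text, cfg):
        return ClassifiedQuestion(text, features, GREETING, None, [], "greeting_rule")

    if detect_repetition(features, context, cfg):
        return ClassifiedQuestion(
            text, features, QuestionType.REPETITION,
            Category.NOT_RECOMMENDED, [], "repetition_rule",
        )

    if model is None:
        raise ValueError("no trained model supplied for a substantive question")
    model_qtype, _scores = model.predict_type(text)
    qtype = suggestive_override(text, model_qtype, context, cfg)
    source = "suggestive_override" if qtype is not model_qtype else "model"
    topics = tag_topics(text, qtype, cfg)
    return ClassifiedQuestion(text, features, qtype, category_of(qtype), topics, source)


def tune_jaccard_threshold(
    pairs: list[tuple[str, str, bool]],
    cfg: FeaturizerConfig | None = None,
    candidates: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 21)),
) -> tuple[float, float]:
    """Sweep thresholds against labeled (previous, current, is_repetition) pairs.

    Returns (best_threshold, accuracy); ties keep the highest threshold
    (most conservative flagging).
    """
    fcfg = cfg or FeaturizerConfig()
    sims = [
        (jaccard(extract_ngrams(a, fcfg), extract_ngrams(b, fcfg)), flag)
        for a, b, flag in pairs
    ]
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = sum((s >= t) == flag for s, flag in sims) / len(sims)
        if acc >= best_acc:
            best_t, best_acc = t, acc
    return best_t, best_acc
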