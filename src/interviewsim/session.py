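"""Interview sessions: run them, record them, summarize them.

A session feeds interviewer questions (scripted or interactive) through
the classification pathway and the avatar answer engine, maintaining the
dialogue context in between, and records a turn-by-turn transcript.
Five outcome measures summarize interviewing quality: counts of
recommended and not-recommended questions, the proportion recommended,
and counts of relevant and incorrect details elicited. Greeting turns
are rapport, not substance, and are excluded from all five.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import numpy as np

from .avatar import INCIDENT_TOPIC, AvatarResponse, ScenarioPack, respond
from .rules import ClassifiedQuestion, DialogueContext, RuleConfig, classify
from .taxonomy import GREETING, Category, QuestionType


@dataclass(frozen=True)
class SessionConfig:
    """Limits and reproducibility knobs for one interview.

    Scripted and test runs bound the interview by ``max_turns`` (the
    deterministic stand-in for the 10-minute wall clock of live
    interviews); interactive runs may bound it by ``time_limit`` seconds.
    """

    max_turns: int | None = 60
    time_limit: float | None = 600.0
    seed: int = 0
    avatar_id: str | None = None

    def __post_init__(self) -> None:
        if self.max_turns is None and self.time_limit is None:
            raise ValueError("set at least one of max_turns / time_limit")


@dataclass
class Turn:
    index: int
    question_text: str
    classified: ClassifiedQuestion
    response: AvatarResponse


@dataclass
class Judgment:
    """Pre/post case assessment: presence call plus confidence (50-100%)."""

    presence: str  # "present" | "absent"
    confidence: int  # one of 50, 60, 70, 80, 90, 100
    narrative: str = ""

    def __post_init__(self) -> None:
        if self.presence not in ("present", "absent"):
            raise ValueError("presence must be 'present' or 'absent'")
        if self.confidence not in (50, 60, 70, 80, 90, 100):
            raise ValueError("confidence must be one of 50,60,70,80,90,100")


@dataclass
class Transcript:
    avatar_id: str
    seed: int
    config: SessionConfig
    turns: list[Turn] = field(default_factory=list)
    pre_judgment: Judgment | None = None
    post_judgment: Judgment | None = None
    truncated: bool = False


@dataclass(frozen=True)
class InterviewSummary:
    """The five outcome measures of one interview."""

    n_recommended: int
    n_not_recommended: int
    prop_recommended: float | None  # %, None when no substantive questions
    n_relevant: int
    n_incorrect: int

    def as_dict(self) -> dict:
        return {
            "n_recommended": self.n_recommended,
            "n_not_recommended": self.n_not_recommended,
            "prop_recommended": self.prop_recommended,
            "n_relevant": self.n_relevant,
            "n_incorrect": self.n_incorrect,
        }


def run_interview(
    questions: Iterable[str],
    pack: ScenarioPack,
    model,
    rules: RuleConfig,
    cfg: SessionConfig | None = None,
) -> Transcript:
    """Run a full interview over a question source.

    Each question is classified in context, answered by the avatar, and
    the context advanced: topics the avatar actually spoke about become
    "mentioned", and the first relevant detail marks the incident topic
    as disclosed (relaxing the suggestive override). Fully reproducible
    for a scripted source and fixed seed.
    """
    cfg = cfg or SessionConfig()
    rng = np.random.default_rng(cfg.seed)
    context = DialogueContext()
    state = pack.fresh_memory()
    transcript = Transcript(avatar_id=pack.profile.avatar_id, seed=cfg.seed, config=cfg)

    iterator: Iterator[str] = iter(questions)
    for text in iterator:
        if cfg.max_turns is not None and len(transcript.turns) >= cfg.max_turns:
            transcript.truncated = True
            break
        cq = classify(text, context, model, rules)
        response = respond(cq, pack.profile, state, rng)
        transcript.turns.append(Turn(len(transcript.turns), text, cq, response))
        produced: set[str] = set()
        if response.detail_kind == "neutral":
            produced |= set(cq.topics)
        if response.detail_kind == "relevant":
            produced.add(INCIDENT_TOPIC)
        context.advance(cq.features, produced)
    return transcript


def summarize(t: Transcript) -> InterviewSummary:
    """Compute the five outcome measures over substantive (non-greeting) turns."""
    n_rec = n_not = n_rel = n_inc = 0
    for turn in t.turns:
        if turn.classified.is_greeting:
            continue
        if turn.classified.category is Category.RECOMMENDED:
            n_rec += 1
        else:
            n_not += 1
        if turn.response.detail_kind == "relevant":
            n_rel += 1
        elif turn.response.detail_kind == "incorrect":
            n_inc += 1
    denom = n_rec + n_not
    prop = 100.0 * n_rec / denom if denom else None
    return InterviewSummary(n_rec, n_not, prop, n_rel, n_inc)


# ---------------------------------------------------------- scripted sources

def simulate_interviewer(
    n_questions: int,
    p_recommended: float,
    rng: np.random.Generator,
    recommended_templates: list[str] | None = None,
    not_recommended_templates: list[str] | None = None,
) -> list[str]:
    """Draw a scripted question list from template banks.

    Each question is a recommended-type template with probability
    ``p_recommended``, else a not-recommended one; used for in-silico
    experiments relating questioning style to elicited details.
    """
    if not (0 <= p_recommended <= 1):
        raise ValueError("p_recommended must be in [0, 1]")
    if recommended_templates is None or not_recommended_templates is None:
        from .synthcorpus import interviewer_templates

        rec, notrec = interviewer_templates()
        recommended_templates = recommended_templates or rec
        not_recommended_templates = not_recommended_templates or notrec
    out = []
    for _ in range(n_questions):
        bank = (
            recommended_templates
            if rng.random() < p_recommended
            else not_recommended_templates
        )
        out.append(bank[int(rng.integers(len(bank)))])
    return out


# --------------------------------------------------------------- transcript IO

def write_transcript_jsonl(t: Transcript, path: str) -> None:
    """One header record then one record per turn."""
    with open(path, "w", encoding="utf-8") as fh:
        header = {
            "record": "header",
            "avatar_id": t.avatar_id,
            "seed": t.seed,
            "max_turns": t.config.max_turns,
            "time_limit": t.config.time_limit,
            "truncated": t.truncated,
            "pre_judgment": _judgment_dict(t.pre_judgment),
            "post_judgment": _judgment_dict(t.post_judgment),
        }
        fh.write(json.dumps(header, ensure_ascii=False) + "\n")
        for turn in t.turns:
            qt = turn.classified.qtype
            rec = {
                "record": "turn",
                "index": turn.index,
                "question": turn.question_text,
                "qtype": qt.value if isinstance(qt, QuestionType) else qt,
                "category": (
                    turn.classified.category.value if turn.classified.category else None
                ),
                "topics": turn.classified.topics,
                "source": turn.classified.source,
                "features": turn.classified.features,
                "answer": turn.response.text,
                "detail_kind": turn.response.detail_kind,
                "conclusive": turn.response.conclusive,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_transcript_jsonl(path: str) -> Transcript:
    with open(path, encoding="utf-8") as fh:
        records = [json.loads(line) for line in fh if line.strip()]
    if not records or records[0].get("record") != "header":
        raise ValueError(f"{path}: missing transcript header record")
    h = records[0]
    cfg = SessionConfig(
        max_turns=h.get("max_turns"), time_limit=h.get("time_limit"), seed=h["seed"]
    )
    t = Transcript(
        avatar_id=h["avatar_id"],
        seed=h["seed"],
        config=cfg,
        truncated=h.get("truncated", False),
        pre_judgment=_judgment_from(h.get("pre_judgment")),
        post_judgment=_judgment_from(h.get("post_judgment")),
    )
    for rec in records[1:]:
        qtype = rec["qtype"] if rec["qtype"] == GREETING else QuestionType(rec["qtype"])
        cq = ClassifiedQuestion(
            text=rec["question"],
            features=rec["features"],
            qtype=qtype,
            category=Category(rec["category"]) if rec["category"] else None,
            topics=list(rec.get("topics", [])),
            source=rec["source"],
        )
        resp = AvatarResponse(rec["answer"], rec["detail_kind"], rec.get("conclusive", False))
        t.turns.append(Turn(rec["index"], rec["question"], cq, resp))
    return t


def _judgment_dict(j: Judgment | None) -> dict | None:
    if j is None:
        return None
    return {"presence": j.presence, "confidence": j.confidence, "narrative": j.narrative}


def _judgment_from(d: dict | None) -> Judgment | None:
    if d is None:
        return None
    return Judgment(**d)
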