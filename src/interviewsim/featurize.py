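"""N-gram featurization of interviewer utterances.

Questions are represented by frequency counts of contiguous character or
word N-grams (default: characters, N = 1-5, the appropriate unit for
languages written without whitespace). The same feature sets drive both
classification (as frequencies) and repetition detection (as presence /
absence via the Jaccard coefficient).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


class EmptyInputError(ValueError):
    """Raised when an utterance is empty after normalization."""


_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class FeaturizerConfig:
    """How utterances are turned into N-gram features.

    Parameters
    ----------
    unit:
        ``"character"`` (default; whitespace removed, each remaining
        character a token) or ``"word"`` (whitespace tokenization).
    n_min, n_max:
        Inclusive N-gram size range; defaults 1-5.
    lowercase:
        Case-fold before extraction.
    vocabulary:
        Optional fixed, ordered N-gram list; when set, ``vectorize`` keeps
        exactly these columns and drops out-of-vocabulary N-grams.
    min_document_frequency:
        Drop N-grams occurring in fewer documents when building a
        vocabulary from a corpus (default 1 = keep everything).
    """

    unit: str = "character"
    n_min: int = 1
    n_max: int = 5
    lowercase: bool = True
    vocabulary: tuple[str, ...] | None = None
    min_document_frequency: int = 1

    def __post_init__(self) -> None:
        if self.unit not in ("character", "word"):
            raise ValueError(f"unit must be 'character' or 'word', got {self.unit!r}")
        if not (1 <= self.n_min <= self.n_max):
            raise ValueError(f"need 1 <= n_min <= n_max, got {self.n_min}..{self.n_max}")
        if self.vocabulary is not None:
            vocab = tuple(self.vocabulary)
            if len(set(vocab)) != len(vocab):
                raise ValueError("vocabulary entries must be unique")
            object.__setattr__(self, "vocabulary", vocab)

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "n_min": self.n_min,
            "n_max": self.n_max,
            "lowercase": self.lowercase,
            "min_document_frequency": self.min_document_frequency,
        }

    @classmethod
    def from_dict(cls, d: dict, vocabulary: tuple[str, ...] | None = None) -> "FeaturizerConfig":
        return cls(vocabulary=vocabulary, **d)


def normalize(text: str, cfg: FeaturizerConfig) -> str:
    """NFKC-normalize, optionally case-fold, and strip punctuation."""
    t = unicodedata.normalize("NFKC", text)
    if cfg.lowercase:
        t = t.lower()
    t = _PUNCT_RE.sub(" ", t)
    return _WS_RE.sub(" ", t).strip()


def tokenize(text: str, cfg: FeaturizerConfig) -> list[str]:
    norm = normalize(text, cfg)
    if not norm:
        raise EmptyInputError(f"utterance is empty after normalization: {text!r}")
    if cfg.unit == "word":
        return norm.split(" ")
    return list(norm.replace(" ", ""))


def extract_ngrams(text: str, cfg: FeaturizerConfig | None = None) -> dict[str, int]:
    """Frequency counts of all N-grams, N in [n_min, n_max].

    Word N-grams are joined with single spaces ("tell me"); character
    N-grams are concatenated. Windows longer than the token sequence
    contribute nothing.
    """
    cfg = cfg or FeaturizerConfig()
    tokens = tokenize(text, cfg)
    sep = " " if cfg.unit == "word" else ""
    counts: dict[str, int] = {}
    for n in range(cfg.n_min, cfg.n_max + 1):
        for i in range(len(tokens) - n + 1):
            gram = sep.join(tokens[i : i + n])
            counts[gram] = counts.get(gram, 0) + 1
    return counts


def build_vocabulary(texts: list[str], cfg: FeaturizerConfig) -> tuple[str, ...]:
    """Ordered vocabulary over a corpus: first-seen order, min-df filtered."""
    order: list[str] = []
    docfreq: dict[str, int] = {}
    for text in texts:
        grams = extract_ngrams(text, cfg)
        for g in grams:
            if g not in docfreq:
                order.append(g)
                docfreq[g] = 0
            docfreq[g] += 1
    if cfg.min_document_frequency > 1:
        order = [g for g in order if docfreq[g] >= cfg.min_document_frequency]
    return tuple(order)


def vectorize(
    texts: list[str], cfg: FeaturizerConfig | None = None
) -> tuple[sparse.csr_matrix, tuple[str, ...]]:
    """Assemble the corpus feature matrix (rows = texts, cols = vocabulary).

    Uses ``cfg.vocabulary`` when given, else builds one from ``texts``.
    Out-of-vocabulary N-grams are dropped.
    """
    cfg = cfg or FeaturizerConfig()
    if not texts:
        raise EmptyInputError("empty corpus")
    vocab = cfg.vocabulary if cfg.vocabulary is not None else build_vocabulary(texts, cfg)
    index = {g: j for j, g in enumerate(vocab)}
    data: list[int] = []
    indices: list[int] = []
    indptr = [0]
    for text in texts:
        for g, c in extract_ngrams(text, cfg).items():
            j = index.get(g)
            if j is not None:
                indices.append(j)
                data.append(c)
        indptr.append(len(indices))
    mat = sparse.csr_matrix(
        (np.asarray(data, dtype=np.float64), indices, indptr),
        shape=(len(texts), len(vocab)),
    )
    mat.sum_duplicates()
    return mat, tuple(vocab)


def jaccard(a: dict[str, int], b: dict[str, int]) -> float:
    """Jaccard coefficient of two feature sets (presence/absence only).

    |keys(a) ∩ keys(b)| / |keys(a) ∪ keys(b)|; 0 when both are empty,
    so two empty utterances are never declared repetitions.
    """
    ka, kb = set(a), set(b)
    union = ka | kb
    if not union:
        return 0.0
    return len(ka & kb) / len(union)


@dataclass
class VocabularyFile:
    """Persist a vocabulary as ordered newline-delimited text."""

    path: str

    def write(self, vocab: tuple[str, ...]) -> None:
        with open(self.path, "w", encoding="utf-8") as fh:
            for g in vocab:
                fh.write(g + "\n")

    def read(self) -> tuple[str, ...]:
        with open(self.path, encoding="utf-8") as fh:
            return tuple(line.rstrip("\n") for line in fh if line.rstrip("\n"))
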