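"""Agreement statistics and batch analytics.

Percent agreement and Cohen's kappa (with a large-sample 95% CI) compare
two coders — typically a human and the automated pathway — over the same
question sequence, either on the full 11-type label space or collapsed
to the recommended / not-recommended categories. Greeting-labeled turns
fall outside the taxonomy and are excluded. Batch correlations relate
questioning style to elicited details across many interviews.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .session import InterviewSummary
from .taxonomy import GREETING, category_of


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class AgreementResult:
    n_items: int
    percent_agreement: float
    kappa: float | None
    kappa_se: float | None
    kappa_ci95: tuple[float, float] | None
    label_space: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "n_items": self.n_items,
            "percent_agreement": self.percent_agreement,
            "kappa": self.kappa,
            "kappa_se": self.kappa_se,
            "kappa_ci95": list(self.kappa_ci95) if self.kappa_ci95 else None,
            "label_space": list(self.label_space),
        }


def _clean(a: list[str], b: list[str]) -> tuple[list[str], list[str]]:
    if len(a) != len(b):
        raise AgreementError(f"label sequences differ in length: {len(a)} vs {len(b)}")
    pairs = [(x, y) for x, y in zip(a, b) if x != GREETING and y != GREETING]
    if not pairs:
        raise AgreementError("no substantive (non-greeting) items to compare")
    xs, ys = zip(*pairs)
    return list(xs), list(ys)


def percent_agreement(a: list[str], b: list[str]) -> float:
    """100 x (matching items / items), greeting turns excluded."""
    xs, ys = _clean(a, b)
    return 100.0 * sum(x == y for x, y in zip(xs, ys)) / len(xs)


def cohens_kappa(a: list[str], b: list[str], collapse: bool = False) -> AgreementResult:
    """Chance-corrected agreement between two label sequences.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement p_e from the
    coders' marginal label distributions. The 95% CI uses the standard
    large-sample standard error sqrt(p_o(1-p_o) / (n (1-p_e)^2)). With
    ``collapse=True`` labels are first mapped to their two-way category.
    When both coders use one identical constant label kappa is undefined
    and reported as None.
    """
    xs, ys = _clean(a, b)
    if collapse:
        xs = [category_of(x).value for x in xs]
        ys = [category_of(y).value for y in ys]
    labels = tuple(sorted(set(xs) | set(ys)))
    n = len(xs)
    p_o = sum(x == y for x, y in zip(xs, ys)) / n
    if len(labels) < 2:
        return AgreementResult(n, 100.0 * p_o, None, None, None, labels)
    # expected agreement from marginal products
    pa = np.array([xs.count(l) / n for l in labels])
    pb = np.array([ys.count(l) / n for l in labels])
    p_e = float(pa @ pb)
    kappa = float(cohen_kappa_score(xs, ys, labels=list(labels)))
    se = float(np.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))) if p_e < 1 else None
    ci = None
    if se is not None:
        z = stats.norm.ppf(0.975)
        ci = (kappa - z * se, kappa + z * se)
    return AgreementResult(n, 100.0 * p_o, kappa, se, ci, labels)


_QUESTION_VARS = ("n_recommended", "n_not_recommended", "prop_recommended")
_DETAIL_VARS = ("n_relevant", "n_incorrect")


def batch_correlations(summaries: list[InterviewSummary]) -> pd.DataFrame:
    """Pearson correlations of question-count vs detail-count measures.

    One row per (question variable, detail variable) pair with r and a
    two-sided p-value; cells with zero variance (or fewer than 3 paired
    observations) are reported as missing.
    """
    if len(summaries) < 3:
        raise AgreementError("need at least 3 interview summaries")
    df = pd.DataFrame([s.as_dict() for s in summaries])
    rows = []
    for q in _QUESTION_VARS:
        for d in _DETAIL_VARS:
            sub = df[[q, d]].dropna()
            r = p = np.nan
            if len(sub) >= 3 and sub[q].std() > 0 and sub[d].std() > 0:
                r, p = stats.pearsonr(sub[q], sub[d])
            rows.append({"question_var": q, "detail_var": d, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)
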