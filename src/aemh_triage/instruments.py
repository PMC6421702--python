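"""Scoring of the evaluation's measurement instruments.

Outcome measures are 7-point Likert responses (1..7) centred at the
neutral midpoint, ``centered = raw - 4``, so scores live in -3..3 and a
score of 0 means "neutral"; deviation from 0 is the quantity the analyses
test.  Intention to self-refer (ISR) and intention to contact the agent
again (ICAA) are single items; feeling of being heard (FBH) is the mean of
seven centred items.  The Insomnia Severity Index (ISI) is a 7-item 0..4
questionnaire totalling 0..28 with four severity bands.  Scale internal
consistency is Cronbach's alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from aemh_triage.errors import InputError, ReliabilityUndefinedError

__all__ = [
    "ISI_BANDS",
    "ScaleReliability",
    "score_isi",
    "center_likert",
    "score_fbh",
    "cronbach_alpha",
    "load_fbh_items",
]

#: Standard published ISI severity bands (inclusive edges), configurable.
ISI_BANDS: tuple[tuple[int, int, str], ...] = (
    (0, 7, "no_insomnia"),
    (8, 14, "sub_threshold"),
    (15, 21, "moderate"),
    (22, 28, "severe"),
)


@dataclass(frozen=True)
class ScaleReliability:
    alpha: float
    k: int
    n: int


def score_isi(
    items: Sequence[int], bands: tuple[tuple[int, int, str], ...] = ISI_BANDS
) -> tuple[int, str]:
    """Score a 7-item ISI response: total (0..28) and severity category."""
    items = list(items)
    if len(items) != 7:
        raise InputError(f"ISI needs exactly 7 items, got {len(items)}")
    for v in items:
        if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
            raise InputError(f"ISI items must be integers in 0..4, got {v!r}")
    total = int(sum(items))
    for lo, hi, label in bands:
        if lo <= total <= hi:
            return total, label
    raise InputError(f"ISI total {total} falls outside the configured bands")


def center_likert(raw: int) -> int:
    """Map a 7-point response 1..7 to its centred score -3..3 (4 -> 0)."""
    if not (isinstance(raw, (int, np.integer)) and 1 <= raw <= 7):
        raise InputError(f"Likert responses must be integers in 1..7, got {raw!r}")
    return int(raw) - 4


def score_fbh(items: Sequence[int]) -> float:
    """Mean of the 7 centred feeling-of-being-heard items.

    Missing items are an error — no imputation is attempted.
    """
    items = list(items)
    if len(items) != 7:
        raise InputError(f"FBH needs exactly 7 items, got {len(items)}")
    return float(np.mean([center_likert(v) for v in items]))


def cronbach_alpha(matrix) -> ScaleReliability:
    """Cronbach's alpha of an ``n respondents x k items`` matrix.

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total)), with sample
    (n-1 denominator) variances.  Undefined when the total score has zero
    variance.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise InputError("expected a 2-D respondents x items matrix")
    n, k = X.shape
    if n < 2 or k < 2:
        raise InputError(f"cronbach_alpha needs n >= 2 and k >= 2, got {n} x {k}")
    if np.isnan(X).any():
        raise InputError("matrix contains missing values")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ReliabilityUndefinedError("total-score variance is zero")
    item_var = X.var(axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1.0 - item_var / total_var)
    return ScaleReliability(alpha=float(alpha), k=k, n=n)


def load_fbh_items() -> list[str]:
    """The 7 shipped FBH item texts (synthetic placeholder wording)."""
    with resources.files("aemh_triage.data").joinpath("fbh_items.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return list(json.load(fh)["items"])
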