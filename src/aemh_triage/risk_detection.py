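"""Two-step risk detection for AEMH systems.

Step 1 detects that a risk *might* exist: free-text utterances are screened
against a per-risk keyword/phrase lexicon, and answers to configured
screening questions are checked against their risk-indicating answer sets.

Step 2 decides whether the situation is severe enough to refer to human
care.  When a validated questionnaire with a referral threshold is
configured, a total score at or above the threshold refers.  When no
questionnaire applies, a duration/severity/progression (DSP) rule is used:
each of the three factors is mapped to ``negative`` or ``not_negative`` and
the user is referred when at least *k* of *n* factors are negative
(default 2 of 3).

Questionnaire gating: soliciting a risk questionnaire (e.g. about suicidal
ideation) can itself do harm, so by default questionnaire totals are only
honoured after step 1 has already produced a signal; an ungated total is
flagged in the decision trace and ignored.

Everything risk-specific — lexicon, questions, thresholds, factor level
mappings, the k-of-n rule — lives in :class:`RiskProfile` so the engine
itself stays risk-agnostic and auditable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import yaml

from aemh_triage.errors import ConfigurationError, InputError

__all__ = [
    "FACTORS",
    "FACTOR_LEVELS",
    "DEFAULT_FACTOR_MAP",
    "ScreeningQuestion",
    "RiskProfile",
    "RiskSignal",
    "FactorRating",
    "DetectionDecision",
    "screen_text",
    "screen_answers",
    "questionnaire_refer",
    "count_negatives",
    "dsp_refer",
    "run_detection",
    "load_profile",
]

FACTORS = ("duration", "severity", "progression")

FACTOR_LEVELS: Mapping[str, tuple[str, str, str]] = {
    "duration": ("short", "medium", "long"),
    "severity": ("low", "medium", "high"),
    "progression": ("improving", "stable", "worsening"),
}

#: Default mapping of factor levels to negativity.  Only the worst pole of
#: each factor counts as negative; middle levels deliberately do not refer
#: and the mapping is fully overridable per profile.
DEFAULT_FACTOR_MAP: Mapping[str, Mapping[str, str]] = {
    "duration": {"short": "not_negative", "medium": "not_negative", "long": "negative"},
    "severity": {"low": "not_negative", "medium": "not_negative", "high": "negative"},
    "progression": {"improving": "not_negative", "stable": "not_negative", "worsening": "negative"},
}


@dataclass(frozen=True)
class ScreeningQuestion:
    """A closed screening question with its risk-indicating answer set."""

    question_id: str
    text: str
    risk_answers: tuple[str, ...]

    def __post_init__(self):
        if not self.question_id:
            raise ConfigurationError("screening question needs a question_id")
        if not self.risk_answers:
            raise ConfigurationError(
                f"screening question {self.question_id!r} has an empty risk-answer set"
            )


@dataclass(frozen=True)
class RiskProfile:
    """Per-risk configuration of the two-step detection engine."""

    risk_name: str
    lexicon: tuple[str, ...] = ()
    screening_questions: tuple[ScreeningQuestion, ...] = ()
    questionnaire_id: str | None = None
    questionnaire_threshold: float | None = None
    factor_map: Mapping[str, Mapping[str, str]] = field(
        default_factory=lambda: DEFAULT_FACTOR_MAP
    )
    referral_rule: tuple[int, int] = (2, 3)
    questionnaire_gated: bool = True

    def __post_init__(self):
        if not self.risk_name:
            raise ConfigurationError("risk_name must be non-empty")
        for pattern in self.lexicon:
            if not pattern or not pattern.strip():
                raise ConfigurationError("lexicon patterns must be non-empty")
        if (self.questionnaire_id is None) != (self.questionnaire_threshold is None):
            raise ConfigurationError(
                "questionnaire_threshold must be configured exactly when "
                "questionnaire_id is configured"
            )
        k, n = self.referral_rule
        if not (1 <= k <= n):
            raise ConfigurationError(f"referral rule requires 1 <= k <= n, got ({k}, {n})")
        if n != len(self.factor_map):
            raise ConfigurationError(
                f"referral rule n={n} must equal the number of configured factors "
                f"({len(self.factor_map)})"
            )
        qids = [q.question_id for q in self.screening_questions]
        if len(set(qids)) != len(qids):
            raise ConfigurationError("duplicate screening question ids")

    def question(self, question_id: str) -> ScreeningQuestion:
        for q in self.screening_questions:
            if q.question_id == question_id:
                return q
        raise ConfigurationError(
            f"unknown screening question {question_id!r} for profile {self.risk_name!r}"
        )


@dataclass(frozen=True)
class RiskSignal:
    """One step-1 indication that a risk might exist."""

    profile: str
    source: str  # "text_match" | "screening_answer"
    evidence: str
    position: int

    def __post_init__(self):
        if self.source not in ("text_match", "screening_answer"):
            raise InputError(f"invalid signal source {self.source!r}")
        if not self.evidence:
            raise InputError("signal evidence must be non-empty")


@dataclass(frozen=True)
class FactorRating:
    """A duration/severity/progression rating of the detected situation."""

    duration: str
    severity: str
    progression: str

    def __post_init__(self):
        for factor in FACTORS:
            level = getattr(self, factor)
            if level not in FACTOR_LEVELS[factor]:
                raise InputError(
                    f"{factor} must be one of {FACTOR_LEVELS[factor]}, got {level!r}"
                )

    def level(self, factor: str) -> str:
        return getattr(self, factor)


@dataclass(frozen=True)
class DetectionDecision:
    outcome: str  # "no_risk" | "possible_risk" | "refer"
    fired_rule: str  # "questionnaire_threshold" | "k_of_n_factors" | "none"
    negatives: int
    trace: tuple[Mapping[str, Any], ...]
    signals: tuple[RiskSignal, ...] = ()

    def __post_init__(self):
        if self.outcome == "refer" and self.fired_rule == "none":
            raise InputError("a refer decision must name the rule that fired")

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "fired_rule": self.fired_rule,
            "negatives": self.negatives,
            "signals": [vars(s) for s in self.signals],
            "trace": [dict(t) for t in self.trace],
        }


def screen_text(text: str, profile: RiskProfile) -> list[RiskSignal]:
    """Screen a free-text utterance against the profile lexicon.

    Matching is case-insensitive at word boundaries; every occurrence of
    every pattern yields a signal (overlaps allowed).  Signals are ordered
    by match position, then pattern text, so screening is deterministic.
    """
    if not isinstance(text, str):
        raise InputError("text must be a string")
    hits: list[tuple[int, str, str]] = []
    for pattern in profile.lexicon:
        # plain phrases, not regexes: escape, then require word boundaries
        rx = re.compile(r"\b" + re.escape(pattern.strip()) + r"\b", re.IGNORECASE)
        for m in rx.finditer(text):
            hits.append((m.start(), pattern, m.group(0)))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [
        RiskSignal(profile=profile.risk_name, source="text_match", evidence=matched, position=pos)
        for pos, _pattern, matched in hits
    ]


def screen_answers(answers: Mapping[str, str], profile: RiskProfile) -> list[RiskSignal]:
    """Check closed screening answers against their risk-indicating sets.

    Unknown question ids are a configuration error: the session and the
    profile disagree about which screening questions exist.
    """
    signals = []
    for idx, (question_id, answer) in enumerate(answers.items()):
        question = profile.question(question_id)
        if answer in question.risk_answers:
            signals.append(
                RiskSignal(
                    profile=profile.risk_name,
                    source="screening_answer",
                    evidence=question_id,
                    position=idx,
                )
            )
    return signals


def questionnaire_refer(total: float, threshold: float | None) -> bool:
    """Referral decision from a questionnaire total score.

    The comparison is inclusive (``total >= threshold``): at the exact
    cutoff the engine takes the safer, referring reading.
    """
    if threshold is None:
        raise ConfigurationError("no questionnaire threshold configured")
    return float(total) >= float(threshold)


def count_negatives(
    rating: FactorRating, factor_map: Mapping[str, Mapping[str, str]] = DEFAULT_FACTOR_MAP
) -> int:
    """Count how many of the three DSP factors map to ``negative``."""
    negatives = 0
    for factor, levels in factor_map.items():
        level = rating.level(factor)
        try:
            verdict = levels[level]
        except KeyError:
            raise ConfigurationError(
                f"factor map for {factor!r} has no entry for level {level!r}"
            ) from None
        if verdict not in ("negative", "not_negative"):
            raise ConfigurationError(
                f"factor map for {factor!r}/{level!r} must be 'negative' or "
                f"'not_negative', got {verdict!r}"
            )
        if verdict == "negative":
            negatives += 1
    return negatives


def dsp_refer(
    rating: FactorRating,
    rule: tuple[int, int] = (2, 3),
    factor_map: Mapping[str, Mapping[str, str]] = DEFAULT_FACTOR_MAP,
) -> tuple[bool, int]:
    """Apply the k-of-n duration/severity/progression rule.

    Returns ``(refer, negatives)`` where ``refer`` is true iff at least
    ``k`` of the ``n`` configured factors are negative.
    """
    k, n = rule
    if not (1 <= k <= n):
        raise ConfigurationError(f"referral rule requires 1 <= k <= n, got ({k}, {n})")
    negatives = count_negatives(rating, factor_map)
    return negatives >= k, negatives


def _rating_from_obs(obs: Mapping[str, Any]) -> FactorRating:
    try:
        return FactorRating(
            duration=obs["duration"], severity=obs["severity"], progression=obs["progression"]
        )
    except KeyError as exc:
        raise InputError(f"factor rating observation missing field {exc}") from None


def run_detection(session: Iterable[Mapping[str, Any]], profile: RiskProfile) -> DetectionDecision:
    """Run the full two-step detection over an ordered session stream.

    ``session`` is a finite iterable of typed observations::

        {"type": "utterance", "text": ...}
        {"type": "screening_answer", "question": ..., "answer": ...}
        {"type": "questionnaire_total", "questionnaire": ..., "total": ...}
        {"type": "factor_rating", "duration": ..., "severity": ..., "progression": ...}

    Outcome is ``no_risk`` when step 1 produced no signal; otherwise a
    configured questionnaire total decides (threshold rule), else a factor
    rating decides (k-of-n rule), else the decision stays ``possible_risk``.
    With ``questionnaire_gated`` (the default), a questionnaire total seen
    *before* any step-1 signal is flagged in the trace and ignored.
    """
    trace: list[dict[str, Any]] = []
    signals: list[RiskSignal] = []
    questionnaire_total: float | None = None
    rating: FactorRating | None = None

    for position, obs in enumerate(session):
        kind = obs.get("type")
        if kind == "utterance":
            found = screen_text(obs.get("text", ""), profile)
            found = [
                RiskSignal(s.profile, s.source, s.evidence, position) for s in found
            ]
            signals.extend(found)
            trace.append(
                {"check": "screen_text", "position": position, "n_signals": len(found)}
            )
        elif kind == "screening_answer":
            found = screen_answers({obs["question"]: obs["answer"]}, profile)
            found = [
                RiskSignal(s.profile, s.source, s.evidence, position) for s in found
            ]
            signals.extend(found)
            trace.append(
                {
                    "check": "screen_answer",
                    "position": position,
                    "question": obs["question"],
                    "n_signals": len(found),
                }
            )
        elif kind == "questionnaire_total":
            if profile.questionnaire_gated and not signals:
                # gating violation: total solicited before any step-1 signal
                trace.append(
                    {
                        "check": "questionnaire_total",
                        "position": position,
                        "gating_violation": True,
                        "used": False,
                    }
                )
                continue
            questionnaire_total = float(obs["total"])
            trace.append(
                {
                    "check": "questionnaire_total",
                    "position": position,
                    "total": questionnaire_total,
                    "used": True,
                }
            )
        elif kind == "factor_rating":
            rating = _rating_from_obs(obs)
            trace.append({"check": "factor_rating", "position": position})
        else:
            raise InputError(f"unknown observation type {kind!r} at position {position}")

    if not signals:
        trace.append({"check": "step1", "result": "no_signal"})
        return DetectionDecision("no_risk", "none", 0, tuple(trace))

    trace.append({"check": "step1", "result": "signal", "n_signals": len(signals)})

    if questionnaire_total is not None and profile.questionnaire_threshold is not None:
        refer = questionnaire_refer(questionnaire_total, profile.questionnaire_threshold)
        trace.append(
            {
                "check": "questionnaire_threshold",
                "total": questionnaire_total,
                "threshold": profile.questionnaire_threshold,
                "refer": refer,
            }
        )
        if refer:
            return DetectionDecision(
                "refer", "questionnaire_threshold", 0, tuple(trace), tuple(signals)
            )
        return DetectionDecision("possible_risk", "none", 0, tuple(trace), tuple(signals))

    if rating is not None:
        refer, negatives = dsp_refer(rating, profile.referral_rule, profile.factor_map)
        trace.append(
            {
                "check": "k_of_n_factors",
                "negatives": negatives,
                "rule": list(profile.referral_rule),
                "refer": refer,
            }
        )
        if refer:
            return DetectionDecision(
                "refer", "k_of_n_factors", negatives, tuple(trace), tuple(signals)
            )
        return DetectionDecision(
            "possible_risk", "none", negatives, tuple(trace), tuple(signals)
        )

    trace.append({"check": "step2", "result": "no_severity_information"})
    return DetectionDecision("possible_risk", "none", 0, tuple(trace), tuple(signals))


def load_profile(path_or_stream) -> RiskProfile:
    """Load a :class:`RiskProfile` from a YAML or JSON mapping."""
    if hasattr(path_or_stream, "read"):
        raw = path_or_stream.read()
    else:
        with open(path_or_stream, "r", encoding="utf-8") as fh:
            raw = fh.read()
    try:
        data = yaml.safe_load(raw)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse profile: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigurationError("profile file must contain a mapping")
    return profile_from_dict(data)


def profile_from_dict(data: Mapping[str, Any]) -> RiskProfile:
    questions = tuple(
        ScreeningQuestion(
            question_id=q["question_id"],
            text=q.get("text", ""),
            risk_answers=tuple(q["risk_answers"]),
        )
        for q in data.get("screening_questions", [])
    )
    factor_map = data.get("factor_map")
    if factor_map is None:
        factor_map = DEFAULT_FACTOR_MAP
    else:
        factor_map = {f: dict(levels) for f, levels in factor_map.items()}
    rule = tuple(data.get("referral_rule", (2, 3)))
    return RiskProfile(
        risk_name=data.get("risk_name", ""),
        lexicon=tuple(data.get("lexicon", ())),
        screening_questions=questions,
        questionnaire_id=data.get("questionnaire_id"),
        questionnaire_threshold=data.get("questionnaire_threshold"),
        factor_map=factor_map,
        referral_rule=rule,  # type: ignore[arg-type]
        questionnaire_gated=bool(data.get("questionnaire_gated", True)),
    )


def read_session(path_or_stream) -> list[dict]:
    """Read a session stream from JSON Lines (one observation per line)."""
    if hasattr(path_or_stream, "read"):
        lines = path_or_stream.read().splitlines()
    else:
        with open(path_or_stream, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    return [json.loads(line) for line in lines if line.strip()]
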