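"""Synthetic replication of the 3x3x3 within-subject evaluation design.

Each simulated participant is randomly assigned a main concern (money /
travel time / stigma), a gender, an age and an Insomnia Severity Index
response, draws a Gaussian random intercept, and then completes three
scenario-chats sampled without replacement from the situation x strategy
crossing (9 stance/severity situations x 3 agent strategies = 27 cells by
default; a restricted 21-cell mode is available because the evaluated
design is reported ambiguously as both 27 and 21).

Outcomes (ISR, ICAA, FBH) are generated on the centred -3..3 scale from a
Gaussian latent variable::

    latent = grand_mean + situation_effect + strategy_effect
             [+ interaction] [+ gender shift, FBH only]
             + participant_intercept + residual

discretised by rounding (half-to-even) and clamping to -3..3.  FBH is
produced as 7 items sharing the scenario-level latent plus item noise, so
the scale is internally consistent the way a real multi-item scale is.
Manipulation-check answers equal the scripted severity/stance level with
probability ``manipulation_fidelity``, otherwise a uniformly chosen other
level.

The generator is fully reproducible from its seed, and its defaults mirror
the evaluated study's conditions: n = 160 participants x 3 chats, concern
distribution 128/15/17, gender distribution 91/67/2, ISI mean 17 (SD 6.5),
outcome grand means 0.76 / -0.03 / 0.79.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from aemh_triage.errors import ConfigurationError, DesignError
from aemh_triage.instruments import ISI_BANDS
from aemh_triage.referral_motivation import STRATEGIES, classify_situation

__all__ = [
    "OUTCOMES",
    "GENDERS",
    "DesignConfig",
    "RespondentModel",
    "crossing_cells",
    "generate_trial",
    "summarize_trial",
]

OUTCOMES = ("isr", "icaa", "fbh")
GENDERS = ("female", "male", "other")
CONCERNS = ("money", "time", "stigma")

_SEVERITY_BY_ROW = ("high", "medium", "low")
_STANCE_BY_COL = ("negative", "doubting", "positive")


def _situation_levels(sid: int) -> tuple[str, str]:
    row, col = divmod(sid - 1, 3)
    return _STANCE_BY_COL[col], _SEVERITY_BY_ROW[row]


def _graded_effects(stance_step: float, severity_step: float) -> np.ndarray:
    """A sum-to-zero 9-vector additive in stance and severity gradients."""
    eff = np.empty(9)
    for sid in range(1, 10):
        stance, severity = _situation_levels(sid)
        eff[sid - 1] = stance_step * (_STANCE_BY_COL.index(stance) - 1) + severity_step * (
            {"low": -1, "medium": 0, "high": 1}[severity]
        )
    return eff - eff.mean()


@dataclass(frozen=True)
class DesignConfig:
    """Design of the simulated trial (defaults: the evaluated study)."""

    n_participants: int = 160
    scenarios_per_participant: int = 3
    crossing: str = "full_27"  # or "restricted"
    seed: int = 0
    concern_probs: Mapping[str, float] = field(
        default_factory=lambda: {"money": 128 / 160, "time": 15 / 160, "stigma": 17 / 160}
    )

    def __post_init__(self):
        if self.n_participants < 1 or self.scenarios_per_participant < 1:
            raise ConfigurationError("counts must be positive")
        if self.crossing not in ("full_27", "restricted"):
            raise ConfigurationError(f"unknown crossing {self.crossing!r}")
        probs = dict(self.concern_probs)
        if set(probs) != set(CONCERNS):
            raise ConfigurationError(f"concern_probs must cover exactly {CONCERNS}")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("concern_probs must sum to 1 (within 1e-9)")
        if self.scenarios_per_participant > len(crossing_cells(self.crossing)):
            raise DesignError(
                f"{self.scenarios_per_participant} distinct scenario cells requested "
                f"but the {self.crossing} crossing has only "
                f"{len(crossing_cells(self.crossing))}"
            )


def crossing_cells(crossing: str = "full_27") -> list[tuple[int, str]]:
    """The (situation id, strategy) cells a scenario-chat is drawn from.

    ``restricted`` drops the facilitate-redundant cells — non-facilitate
    strategies in accept-care situations {3, 6, 9} — leaving 21 cells; it
    exists because the evaluated design is reported inconsistently (27
    situation x strategy combinations vs "21 possible combinations").
    """
    cells = [(sid, strat) for sid in range(1, 10) for strat in STRATEGIES]
    if crossing == "full_27":
        return cells
    if crossing == "restricted":
        accept_care = {3, 6, 9}
        return [
            (sid, strat)
            for sid, strat in cells
            if not (sid in accept_care and strat != "facilitate")
        ]
    raise ConfigurationError(f"unknown crossing {crossing!r}")


def _check_sum_zero(name: str, vec: np.ndarray, size: int):
    if vec.shape != (size,):
        raise ConfigurationError(f"{name} must have shape ({size},), got {vec.shape}")
    if abs(vec.sum()) > 1e-8:
        raise ConfigurationError(f"{name} must be sum-to-zero coded")


@dataclass(frozen=True)
class RespondentModel:
    """Population model the synthetic respondents are drawn from."""

    grand_means: Mapping[str, float] = field(
        default_factory=lambda: {"isr": 0.76, "icaa": -0.03, "fbh": 0.79}
    )
    situation_effects: Mapping[str, np.ndarray] = field(
        default_factory=lambda: {
            "isr": _graded_effects(0.40, 0.20),
            "icaa": _graded_effects(0.15, 0.10),
            "fbh": _graded_effects(0.15, 0.05),
        }
    )
    strategy_effects: Mapping[str, np.ndarray] = field(
        # order follows STRATEGIES = (facilitate, persuade, accept_rejection)
        default_factory=lambda: {
            "isr": np.array([0.05, 0.35, -0.40]),
            "icaa": np.array([-0.25, 0.25, 0.00]),
            "fbh": np.array([-0.35, 0.30, 0.05]),
        }
    )
    interaction: Mapping[str, np.ndarray] | None = None  # outcome -> 9x3
    sigma_participant: float = 1.0
    sigma_residual: float = 1.4
    fbh_item_sigma: float = 1.0
    manipulation_fidelity: float = 0.68
    gender_probs: Mapping[str, float] = field(
        default_factory=lambda: {"female": 91 / 160, "male": 67 / 160, "other": 2 / 160}
    )
    gender_fbh_shift: Mapping[str, float] = field(
        default_factory=lambda: {"female": -0.25, "male": 0.36, "other": -0.50}
    )
    age_mean: float = 36.0
    age_sd: float = 10.41
    isi_mean: float = 17.0
    isi_sd: float = 6.53

    def __post_init__(self):
        if self.sigma_participant < 0 or self.sigma_residual < 0 or self.fbh_item_sigma < 0:
            raise ConfigurationError("SDs must be non-negative")
        if not (0.0 <= self.manipulation_fidelity <= 1.0):
            raise ConfigurationError("manipulation_fidelity must be in [0, 1]")
        for outcome in OUTCOMES:
            _check_sum_zero(
                f"situation_effects[{outcome}]",
                np.asarray(self.situation_effects[outcome], float),
                9,
            )
            _check_sum_zero(
                f"strategy_effects[{outcome}]",
                np.asarray(self.strategy_effects[outcome], float),
                3,
            )
        if abs(sum(self.gender_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("gender_probs must sum to 1")

    @classmethod
    def null(cls, sigma_participant: float = 1.0, sigma_residual: float = 1.4, **kw):
        """A zero-effect model (grand means and all effects zero)."""
        zeros9 = {o: np.zeros(9) for o in OUTCOMES}
        zeros3 = {o: np.zeros(3) for o in OUTCOMES}
        return cls(
            grand_means={o: 0.0 for o in OUTCOMES},
            situation_effects=zeros9,
            strategy_effects=zeros3,
            sigma_participant=sigma_participant,
            sigma_residual=sigma_residual,
            gender_fbh_shift={g: 0.0 for g in GENDERS},
            **kw,
        )

    def with_strategy_effect(self, outcome: str, effects: Sequence[float]) -> "RespondentModel":
        eff = dict(self.strategy_effects)
        eff[outcome] = np.asarray(effects, float)
        return replace(self, strategy_effects=eff)


def _discretize(latent: np.ndarray) -> np.ndarray:
    """Round (half-to-even) and clamp a latent score to the -3..3 scale."""
    return np.clip(np.rint(latent), -3, 3).astype(int)


def _perceive(rng: np.random.Generator, scripted: np.ndarray, levels: Sequence[str], fidelity: float):
    """Scripted level with prob. fidelity, else a uniform *other* level."""
    n = len(scripted)
    faithful = rng.random(n) < fidelity
    out = np.array(scripted, dtype=object)
    for i in np.flatnonzero(~faithful):
        others = [lv for lv in levels if lv != scripted[i]]
        out[i] = others[rng.integers(len(others))]
    return out


def generate_trial(
    design: DesignConfig = DesignConfig(),
    model: RespondentModel = RespondentModel(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a long-format synthetic trial dataset (one row per chat)."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    cells = crossing_cells(design.crossing)
    n_p, n_s = design.n_participants, design.scenarios_per_participant

    concerns = rng.choice(CONCERNS, size=n_p, p=[design.concern_probs[c] for c in CONCERNS])
    genders = rng.choice(GENDERS, size=n_p, p=[model.gender_probs[g] for g in GENDERS])
    ages = np.clip(np.rint(rng.normal(model.age_mean, model.age_sd, n_p)), 18, 80).astype(int)
    isi_latent = rng.normal(model.isi_mean, model.isi_sd, n_p)
    # distribute the latent total over 7 items with item noise, then re-total
    isi_items = np.clip(
        np.rint(isi_latent[:, None] / 7 + rng.normal(0, 0.6, (n_p, 7))), 0, 4
    ).astype(int)
    isi_totals = isi_items.sum(axis=1)
    intercepts = rng.normal(0.0, model.sigma_participant, n_p)

    rows: list[dict] = []
    for p in range(n_p):
        chosen = rng.choice(len(cells), size=n_s, replace=False)
        isi_total = int(isi_totals[p])
        isi_cat = next(label for lo, hi, label in ISI_BANDS if lo <= isi_total <= hi)
        for s_idx, cell in enumerate(chosen, start=1):
            sid, strategy = cells[cell]
            stance, severity = _situation_levels(sid)
            row = {
                "participant_id": p + 1,
                "scenario_index": s_idx,
                "situation": sid,
                "stance": stance,
                "severity": severity,
                "sit_type": classify_situation(stance, severity).sit_type,
                "strategy": strategy,
                "concern": concerns[p],
                "gender": genders[p],
                "age": int(ages[p]),
                "isi_total": isi_total,
                "isi_category": isi_cat,
            }
            strat_idx = STRATEGIES.index(strategy)
            for outcome in OUTCOMES:
                mu = (
                    model.grand_means[outcome]
                    + float(np.asarray(model.situation_effects[outcome])[sid - 1])
                    + float(np.asarray(model.strategy_effects[outcome])[strat_idx])
                    + intercepts[p]
                )
                if model.interaction is not None and outcome in model.interaction:
                    mu += float(np.asarray(model.interaction[outcome])[sid - 1, strat_idx])
                if outcome == "fbh":
                    mu += model.gender_fbh_shift.get(genders[p], 0.0)
                    scen_latent = mu + rng.normal(0.0, model.sigma_residual)
                    item_latents = scen_latent + rng.normal(0.0, model.fbh_item_sigma, 7)
                    item_scores = _discretize(item_latents)
                    for j in range(7):
                        row[f"fbh_{j + 1}"] = int(item_scores[j] + 4)  # raw 1..7
                    row["fbh"] = float(item_scores.mean())
                else:
                    latent = mu + rng.normal(0.0, model.sigma_residual)
                    centered = int(_discretize(np.array([latent]))[0])
                    row[f"{outcome}_raw"] = centered + 4
                    row[outcome] = float(centered)
            rows.append(row)

    df = pd.DataFrame(rows)
    df["perceived_severity"] = _perceive(
        rng, df["severity"].to_numpy(), _SEVERITY_BY_ROW[::-1], model.manipulation_fidelity
    )
    df["perceived_stance"] = _perceive(
        rng, df["stance"].to_numpy(), _STANCE_BY_COL, model.manipulation_fidelity
    )
    return df


def summarize_trial(df: pd.DataFrame) -> dict:
    """Descriptive summary: centred outcome means/SDs and category counts."""
    per_participant = df.drop_duplicates("participant_id")
    out: dict = {
        "n_records": int(len(df)),
        "n_participants": int(df["participant_id"].nunique()),
        "outcomes": {
            o: {"mean": float(df[o].mean()), "sd": float(df[o].std(ddof=1))}
            for o in OUTCOMES
            if o in df
        },
        "concern_counts": per_participant["concern"].value_counts().to_dict(),
        "gender_counts": per_participant["gender"].value_counts().to_dict(),
    }
    if "isi_category" in df:
        out["isi"] = {
            "mean": float(per_participant["isi_total"].mean()),
            "sd": float(per_participant["isi_total"].std(ddof=1)),
            "category_counts": per_participant["isi_category"].value_counts().to_dict(),
        }
    return out
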