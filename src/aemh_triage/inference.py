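"""Multilevel analysis pipeline for the within-subject evaluation.

Every scenario-chat outcome is analysed with participant as random
intercept, because each participant contributes three correlated
observations.  Hypotheses about fixed effects are tested by comparing
nested maximum-likelihood fits with likelihood-ratio tests (LRTs):
chi2 = 2 (ll1 - ll0), df = difference in parameter count.  All Gaussian
fits use ML, never REML, since REML log-likelihoods of models with
different fixed effects are not comparable.

The four hypothesis ladders:

* **H1** (all data, each outcome): does situation, strategy, or their
  interaction add to the null model?  (For FBH, gender is kept as a fixed
  covariate throughout.)
* **H2** (care-potential situations 1, 2, 5; ISR): does agent strategy
  matter, overall and in the pairwise persuade-vs-other subsets?
* **H3** (accept-care situations 3, 6, 9, facilitate strategy only; ISR):
  does the null-model intercept deviate from the neutral 0?  Reported as a
  Wald F with naive denominator df = participants - 1 (the original df
  convention is not reconstructable and is documented as such).
* **H4** (reject-care situations 4, 7, 8; ICAA and FBH): does strategy
  matter, overall and in the pairwise accept-rejection-vs-other subsets?

The manipulation check asks whether the scripted severity/stance level
predicts the level the participant reports, using a cumulative-link
(proportional-odds) mixed model with participant random intercept,
estimated by ML with Gauss-Hermite quadrature.  Effect size for these
chi-square tests is Cohen's w = sqrt(chi2 / n); pseudo-R2 is reported in
both McFadden and Nagelkerke flavours (the original report's variant is
not identifiable, so neither is privileged).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.regression.mixed_linear_model import MixedLM

from aemh_triage.errors import InputError, RankDeficiencyError, UsageError

__all__ = [
    "ModelSpec",
    "ModelFit",
    "LRTResult",
    "fit_lmm",
    "fit_clmm",
    "lrt",
    "cohen_w",
    "intercept_wald",
    "manipulation_check",
    "run_hypothesis_ladders",
    "covariate_checks",
    "load_trial_csv",
]

GAUSSIAN_OUTCOMES = ("isr", "icaa", "fbh")
ORDINAL_OUTCOMES = ("perceived_severity", "perceived_stance")
_ORDINAL_LEVELS = {
    "perceived_severity": ("low", "medium", "high"),
    "perceived_stance": ("negative", "doubting", "positive"),
}

_CATEGORICAL_TERMS = ("situation", "strategy", "gender", "concern")
_NUMERIC_TERMS = ("age", "isi_total", "scripted")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, fixed terms, family and data subset."""

    outcome: str
    fixed_terms: tuple[str, ...] = ("intercept",)
    family: str = "gaussian"
    group: str = "participant_id"
    subset_situations: tuple[int, ...] | None = None
    subset_strategies: tuple[str, ...] | None = None

    def __post_init__(self):
        if "intercept" not in self.fixed_terms:
            raise InputError("the intercept is always part of the model")
        if "situation:strategy" in self.fixed_terms and not (
            "situation" in self.fixed_terms and "strategy" in self.fixed_terms
        ):
            raise InputError("the interaction requires both main effects")
        if self.family not in ("gaussian", "cumulative_logit"):
            raise InputError(f"unknown family {self.family!r}")
        if self.family == "cumulative_logit" and self.outcome not in ORDINAL_OUTCOMES:
            raise InputError("cumulative_logit is only for ordinal outcomes")


@dataclass(frozen=True)
class ModelFit:
    spec: ModelSpec
    loglik: float
    n_obs: int
    n_groups: int
    n_params: int
    beta: Mapping[str, float]
    beta_se: Mapping[str, float]
    sigma_p: float
    sigma_e: float | None  # residual SD (gaussian); None for ordinal
    thresholds: tuple[float, ...] = ()  # ordinal only
    converged: bool = True
    data_fingerprint: str = ""


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float
    n: int

    def __post_init__(self):
        if self.chi2 < 0 or self.df < 0:
            raise InputError("LRT needs chi2 >= 0 and df >= 0")


def _apply_subset(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = data
    if spec.subset_situations is not None:
        df = df[df["situation"].isin(spec.subset_situations)]
    if spec.subset_strategies is not None:
        df = df[df["strategy"].isin(spec.subset_strategies)]
    if len(df) == 0:
        raise InputError("subset filter removed every observation")
    return df


def _fingerprint(df: pd.DataFrame, spec: ModelSpec) -> str:
    h = hashlib.sha1()
    h.update(pd.util.hash_pandas_object(df[spec.outcome], index=False).to_numpy().tobytes())
    h.update(pd.util.hash_pandas_object(df[spec.group], index=False).to_numpy().tobytes())
    return h.hexdigest()


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    levels = sorted(series.unique(), key=str)
    cols = {}
    for level in levels[1:]:  # first observed level is the reference
        cols[f"{prefix}[{level}]"] = (series == level).astype(float).to_numpy()
    return pd.DataFrame(cols, index=series.index)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Build the fixed-effects design matrix, checking rank term by term.

    Categorical terms are dummy-coded against the first observed level
    (LRTs are invariant to the coding).  A term whose columns do not raise
    the matrix rank by their count is aliased and reported by name.
    """
    blocks: list[tuple[str, pd.DataFrame]] = [
        ("intercept", pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index))
    ]
    for term in spec.fixed_terms:
        if term == "intercept":
            continue
        if term == "situation:strategy":
            sit = _dummies(data["situation"], "situation")
            strat = _dummies(data["strategy"], "strategy")
            cols = {}
            for sc in sit.columns:
                for tc in strat.columns:
                    cols[f"{sc}:{tc}"] = sit[sc].to_numpy() * strat[tc].to_numpy()
            blocks.append((term, pd.DataFrame(cols, index=data.index)))
        elif term in _CATEGORICAL_TERMS:
            blocks.append((term, _dummies(data[term], term)))
        elif term in _NUMERIC_TERMS or pd.api.types.is_numeric_dtype(data[term]):
            blocks.append(
                (term, pd.DataFrame({term: data[term].astype(float)}, index=data.index))
            )
        else:
            blocks.append((term, _dummies(data[term], term)))

    X = pd.concat([b for _, b in blocks], axis=1)
    rank = 0
    ncols = 0
    for term, block in blocks:
        ncols += block.shape[1]
        new_rank = np.linalg.matrix_rank(X.iloc[:, :ncols].to_numpy())
        if new_rank != rank + block.shape[1]:
            raise RankDeficiencyError(term)
        rank = new_rank
    return X


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """ML fit of a Gaussian random-intercept model.

    Returns the marginal log-likelihood, fixed-effect estimates with
    standard errors, and the two variance components (participant SD
    ``sigma_p``, residual SD ``sigma_e``).  The ``converged`` flag reports
    the optimizer's verdict honestly; boundary fits (sigma_p at 0) are
    returned, not hidden.
    """
    if spec.family != "gaussian":
        raise InputError("fit_lmm is for gaussian outcomes; use fit_clmm")
    df = _apply_subset(data, spec)
    y = df[spec.outcome].to_numpy(dtype=float)
    X = build_design(df, spec)
    groups = df[spec.group].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X.to_numpy(), groups=groups)
        try:
            result = model.fit(reml=False, method="bfgs", gtol=1e-12, maxiter=2000)
        except np.linalg.LinAlgError:
            result = model.fit(reml=False, method=["powell", "cg"])
        beta = dict(zip(X.columns, np.asarray(result.fe_params, dtype=float)))
        with np.errstate(invalid="ignore"):
            beta_se = dict(zip(X.columns, np.asarray(result.bse_fe, dtype=float)))
    return ModelFit(
        spec=spec,
        loglik=float(result.llf),
        n_obs=int(len(df)),
        n_groups=int(df[spec.group].nunique()),
        n_params=X.shape[1] + 2,
        beta=beta,
        beta_se=beta_se,
        sigma_p=float(np.sqrt(max(np.asarray(result.cov_re)[0, 0], 0.0))),
        sigma_e=float(np.sqrt(result.scale)),
        converged=bool(result.converged),
        data_fingerprint=_fingerprint(df, spec),
    )


# ---------------------------------------------------------------------------
# cumulative-link mixed model (proportional odds with random intercept)
# ---------------------------------------------------------------------------


def _clmm_nll(params, y, X, group_idx, n_groups, nodes, log_weights):
    """Negative marginal log-likelihood via Gauss-Hermite quadrature.

    Parameters are (a, log_gap, beta..., log_sigma) with thresholds
    theta = (a, a + exp(log_gap)) so ordering is built in.
    """
    a, log_gap = params[0], params[1]
    beta = params[2:-1]
    sigma = np.exp(params[-1])
    theta = np.array([a, a + np.exp(log_gap)])

    eta = X @ beta if X.shape[1] else np.zeros(len(y))
    b = np.sqrt(2.0) * sigma * nodes  # (Q,)
    lin = eta[:, None] + b[None, :]  # (n, Q)

    upper = np.where(y < 2, theta[np.minimum(y, 1)], np.inf)[:, None] - lin
    lower = np.where(y > 0, theta[np.maximum(y - 1, 0)], -np.inf)[:, None] - lin
    prob = special.expit(upper) - special.expit(lower)
    logp = np.log(np.clip(prob, 1e-300, None))

    group_log = np.zeros((n_groups, len(nodes)))
    np.add.at(group_log, group_idx, logp)
    return -float(np.sum(special.logsumexp(group_log + log_weights[None, :], axis=1)))


def fit_clmm(
    data: pd.DataFrame, spec: ModelSpec, n_quad: int = 15, maxiter: int = 500
) -> ModelFit:
    """ML fit of a cumulative-logit (proportional-odds) random-intercept model.

    The ordinal outcome must have 3 levels; the participant random
    intercept is integrated out with ``n_quad``-node Gauss-Hermite
    quadrature.  Non-convergence is reported via the ``converged`` flag and
    a warning, never silently.
    """
    if spec.family != "cumulative_logit":
        raise InputError("fit_clmm requires family='cumulative_logit'")
    df = _apply_subset(data, spec)
    levels = _ORDINAL_LEVELS[spec.outcome]
    y = df[spec.outcome].map({lv: i for i, lv in enumerate(levels)})
    if y.isna().any():
        raise InputError(f"{spec.outcome} contains values outside {levels}")
    y = y.to_numpy(dtype=int)

    X_full = build_design(df, spec)
    X = X_full.drop(columns="intercept")  # thresholds absorb the intercept
    Xn = X.to_numpy(dtype=float)
    groups, group_idx = np.unique(df[spec.group].to_numpy(), return_inverse=True)

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_weights = np.log(weights) - 0.5 * np.log(np.pi)

    # start thresholds at the marginal cumulative logits
    p1 = max(np.mean(y == 0), 1e-3)
    p2 = max(np.mean(y <= 1), p1 + 1e-3)
    a0 = special.logit(min(p1, 1 - 1e-3))
    gap0 = max(special.logit(min(p2, 1 - 1e-3)) - a0, 1e-2)
    x0 = np.concatenate([[a0, np.log(gap0)], np.zeros(Xn.shape[1]), [np.log(0.5)]])

    args = (y, Xn, group_idx, len(groups), nodes, log_weights)
    res = optimize.minimize(
        _clmm_nll, x0, args=args, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-6}
    )
    if not res.success:
        # BFGS sometimes stops with "precision loss" near the optimum;
        # polish with a derivative-free restart before giving a verdict
        hess_inv = res.hess_inv
        polish = optimize.minimize(
            _clmm_nll,
            res.x,
            args=args,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-9},
        )
        if polish.fun <= res.fun:
            res = polish
            res.hess_inv = hess_inv  # keep the curvature approximation for SEs
    converged = bool(res.success) or (
        hasattr(res, "jac") and float(np.max(np.abs(res.jac))) < 1e-3
    )
    if not converged:
        warnings.warn(f"CLMM fit for {spec.outcome} did not converge: {res.message}")

    a, log_gap = res.x[0], res.x[1]
    beta_hat = res.x[2 : 2 + Xn.shape[1]]
    sigma = float(np.exp(res.x[-1]))
    # SEs from the inverse Hessian approximation (adequate for Wald-free use)
    se = np.sqrt(np.maximum(np.diag(res.hess_inv), 0.0))
    beta = dict(zip(X.columns, beta_hat.astype(float)))
    beta_se = dict(zip(X.columns, se[2 : 2 + Xn.shape[1]].astype(float)))
    return ModelFit(
        spec=spec,
        loglik=float(-res.fun),
        n_obs=int(len(df)),
        n_groups=int(len(groups)),
        n_params=2 + Xn.shape[1] + 1,
        beta=beta,
        beta_se=beta_se,
        sigma_p=sigma,
        sigma_e=None,
        thresholds=(float(a), float(a + np.exp(log_gap))),
        converged=converged,
        data_fingerprint=_fingerprint(df, spec),
    )


def lrt(fit0: ModelFit, fit1: ModelFit) -> LRTResult:
    """Likelihood-ratio test of nested ML fits on identical data rows."""
    if fit0.data_fingerprint != fit1.data_fingerprint or fit0.n_obs != fit1.n_obs:
        raise UsageError("LRT requires both models fitted to the same data rows")
    if not set(fit0.spec.fixed_terms) <= set(fit1.spec.fixed_terms):
        raise UsageError("LRT requires fit0 nested in fit1")
    df = fit1.n_params - fit0.n_params
    if df < 0:
        raise UsageError("the nested model cannot have more parameters")
    chi2 = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    # df == 0 only for a model compared with itself: chi2 is 0 and p is 1
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=chi2, df=df, p=p, n=fit0.n_obs)


def cohen_w(chi2: float, n: int) -> float:
    """Cohen's w effect size for a chi-square statistic: sqrt(chi2 / n)."""
    if n <= 0:
        raise InputError("n must be positive")
    if chi2 < 0:
        raise InputError("chi2 must be non-negative")
    return float(np.sqrt(chi2 / n))


def intercept_wald(fit: ModelFit) -> dict:
    """Wald test of the null-model intercept against 0.

    F = (beta0 / se)^2 on (1, n_groups - 1) df.  The denominator df is a
    naive convention, reported as part of the result.
    """
    b = fit.beta["intercept"]
    se = fit.beta_se["intercept"]
    F = float((b / se) ** 2)
    df2 = fit.n_groups - 1
    return {
        "intercept": float(b),
        "se": float(se),
        "F": F,
        "df": (1, df2),
        "p": float(stats.f.sf(F, 1, df2)),
        "n": fit.n_obs,
    }


def _lrt_entry(result: LRTResult) -> dict:
    return {"n": result.n, "chi2": result.chi2, "df": result.df, "p": result.p}


def manipulation_check(data: pd.DataFrame, n_quad: int = 15) -> dict:
    """Did scripted severity/stance predict the perceived level?

    For each check the scripted level is entered as a single linear
    (-1, 0, 1) predictor of the perceived level in a cumulative-logit
    random-intercept model, compared against the thresholds-only null by
    LRT (1 df).  Reports Cohen's w and McFadden / Nagelkerke pseudo-R2.
    """
    out = {}
    for name, scripted_col in (("severity", "severity"), ("stance", "stance")):
        outcome = f"perceived_{scripted_col}"
        levels = _ORDINAL_LEVELS[outcome]
        work = data.copy()
        work["scripted"] = work[scripted_col].map({lv: i - 1 for i, lv in enumerate(levels)})
        null = fit_clmm(
            work, ModelSpec(outcome=outcome, family="cumulative_logit"), n_quad=n_quad
        )
        alt = fit_clmm(
            work,
            ModelSpec(
                outcome=outcome, fixed_terms=("intercept", "scripted"), family="cumulative_logit"
            ),
            n_quad=n_quad,
        )
        test = lrt(null, alt)
        n = test.n
        mcfadden = 1.0 - alt.loglik / null.loglik if null.loglik != 0 else float("nan")
        nagelkerke = (1.0 - np.exp(2.0 * (null.loglik - alt.loglik) / n)) / (
            1.0 - np.exp(2.0 * null.loglik / n)
        )
        out[name] = {
            **_lrt_entry(test),
            "w": cohen_w(test.chi2, n),
            "pseudo_r2_mcfadden": float(mcfadden),
            "pseudo_r2_nagelkerke": float(nagelkerke),
            "beta_scripted": alt.beta["scripted"],
        }
    return out


def _base_terms(outcome: str) -> tuple[str, ...]:
    # gender stays in every FBH model as a fixed covariate
    return ("intercept", "gender") if outcome == "fbh" else ("intercept",)


def _strategy_ladder(
    data: pd.DataFrame,
    outcome: str,
    situations: tuple[int, ...] | None,
    strategies: tuple[str, ...] | None = None,
) -> LRTResult:
    base = _base_terms(outcome)
    null = fit_lmm(
        data,
        ModelSpec(
            outcome=outcome,
            fixed_terms=base,
            subset_situations=situations,
            subset_strategies=strategies,
        ),
    )
    alt = fit_lmm(
        data,
        ModelSpec(
            outcome=outcome,
            fixed_terms=base + ("strategy",),
            subset_situations=situations,
            subset_strategies=strategies,
        ),
    )
    return lrt(null, alt)


CARE_POTENTIAL = (1, 2, 5)
ACCEPT_CARE = (3, 6, 9)
REJECT_CARE = (4, 7, 8)


def run_hypothesis_ladders(data: pd.DataFrame, hypotheses: Sequence[str] = ("h1", "h2", "h3", "h4")) -> dict:
    """Run the H1-H4 model-comparison ladders on a long-format dataset."""
    required = {"participant_id", "situation", "strategy", "isr", "icaa", "fbh", "gender"}
    missing = required - set(data.columns)
    if missing:
        raise InputError(f"data is missing required columns: {sorted(missing)}")
    report: dict[str, Any] = {}

    if "h1" in hypotheses:
        h1 = {}
        for outcome in GAUSSIAN_OUTCOMES:
            base = _base_terms(outcome)
            fits = {
                "m0": fit_lmm(data, ModelSpec(outcome, base)),
                "m1": fit_lmm(data, ModelSpec(outcome, base + ("situation",))),
                "m2": fit_lmm(data, ModelSpec(outcome, base + ("strategy",))),
                "m3": fit_lmm(data, ModelSpec(outcome, base + ("strategy", "situation"))),
                "m4": fit_lmm(
                    data,
                    ModelSpec(
                        outcome, base + ("strategy", "situation", "situation:strategy")
                    ),
                ),
            }
            h1[outcome] = {
                "situation": _lrt_entry(lrt(fits["m0"], fits["m1"])),
                "strategy": _lrt_entry(lrt(fits["m0"], fits["m2"])),
                "interaction": _lrt_entry(lrt(fits["m3"], fits["m4"])),
            }
        report["h1"] = h1

    if "h2" in hypotheses:
        report["h2"] = {
            "strategy": _lrt_entry(_strategy_ladder(data, "isr", CARE_POTENTIAL)),
            "persuade_vs_accept_rejection": _lrt_entry(
                _strategy_ladder(data, "isr", CARE_POTENTIAL, ("persuade", "accept_rejection"))
            ),
            "persuade_vs_facilitate": _lrt_entry(
                _strategy_ladder(data, "isr", CARE_POTENTIAL, ("persuade", "facilitate"))
            ),
        }

    if "h3" in hypotheses:
        null = fit_lmm(
            data,
            ModelSpec(
                outcome="isr",
                fixed_terms=("intercept",),
                subset_situations=ACCEPT_CARE,
                subset_strategies=("facilitate",),
            ),
        )
        report["h3"] = intercept_wald(null)

    if "h4" in hypotheses:
        h4 = {}
        for outcome in ("icaa", "fbh"):
            h4[outcome] = {
                "strategy": _lrt_entry(_strategy_ladder(data, outcome, REJECT_CARE)),
                "accept_rejection_vs_persuade": _lrt_entry(
                    _strategy_ladder(
                        data, outcome, REJECT_CARE, ("accept_rejection", "persuade")
                    )
                ),
                "accept_rejection_vs_facilitate": _lrt_entry(
                    _strategy_ladder(
                        data, outcome, REJECT_CARE, ("accept_rejection", "facilitate")
                    )
                ),
            }
        report["h4"] = h4

    return report


def covariate_checks(
    data: pd.DataFrame,
    covariates: Sequence[str] = ("age", "gender", "isi_total", "concern"),
    outcomes: Sequence[str] = GAUSSIAN_OUTCOMES,
) -> dict:
    """LRT of each covariate's effect on each outcome (random-intercept models).

    A constant covariate cannot be tested and is excluded with a
    diagnostic rather than producing a degenerate fit.
    """
    report: dict[str, Any] = {}
    for cov in covariates:
        if cov not in data.columns:
            report[cov] = {"excluded": True, "reason": "column not present"}
            continue
        if data[cov].nunique() <= 1:
            report[cov] = {"excluded": True, "reason": "covariate is constant"}
            continue
        per_outcome = {}
        for outcome in outcomes:
            null = fit_lmm(data, ModelSpec(outcome, ("intercept",)))
            alt = fit_lmm(data, ModelSpec(outcome, ("intercept", cov)))
            per_outcome[outcome] = _lrt_entry(lrt(null, alt))
        report[cov] = per_outcome
    return report


#: Column mapping for reading an externally deposited dataset into the
#: canonical long format; keys are canonical names, values the file's names.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "participant_id": "participant_id",
    "situation": "situation",
    "strategy": "strategy",
    "isr": "isr",
    "icaa": "icaa",
    "fbh": "fbh",
    "gender": "gender",
}


def load_trial_csv(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a long-format trial CSV, renaming columns to canonical names.

    Raw 1..7 outcome columns (``isr_raw`` etc.) are centred to -3..3 when
    the centred columns are absent, so externally deposited data and the
    simulator's output load identically.
    """
    df = pd.read_csv(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    rename = {src: dst for dst, src in cmap.items() if src in df.columns and src != dst}
    df = df.rename(columns=rename)
    for outcome in ("isr", "icaa"):
        if outcome not in df.columns and f"{outcome}_raw" in df.columns:
            df[outcome] = df[f"{outcome}_raw"].astype(float) - 4.0
    if "fbh" not in df.columns:
        item_cols = [c for c in df.columns if c.startswith("fbh_")]
        if len(item_cols) == 7:
            df["fbh"] = df[item_cols].astype(float).mean(axis=1) - 4.0
    return df
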