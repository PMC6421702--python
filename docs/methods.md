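# Methods

`aemh_triage` packages three safety protocols for autonomous e-mental-health
(AEMH) systems as executable, testable machinery, together with a synthetic
trial generator and the multilevel analysis pipeline used to evaluate the
third protocol. This note records the models, their assumptions, the
parameter choices, and the limits of what the synthetic evaluation shows.

## Risk detection (two-step rule engine)

**Model.** Step 1 detects that a risk *might* exist: keyword/phrase screening
of free text and risk-indicating answers to closed screening questions.
Step 2 decides whether the situation is severe enough to refer: a
questionnaire total compared against a configured threshold when a suitable
instrument exists, otherwise a k-of-n rule over three ordinal factors —
duration (short/medium/long), severity (low/medium/high) and progression
(improving/stable/worsening). Each factor level maps to `negative` or
`not_negative`; with the default map only the worst pole of each factor is
negative, and the default rule refers at 2 of 3 negatives.

**Choices made where the protocol is open.**

* The threshold comparison is inclusive (`total >= threshold`): at the exact
  cutoff the engine takes the safer, referring reading.
* Middle factor levels (medium, stable) do not count as negative by default.
  How such levels should count is genuinely open; the mapping is therefore
  configuration, not code.
* Text matching is case-insensitive, word-boundary, overlapping; lexicons are
  literal phrases rather than regular expressions so that a clinician can
  audit a profile by reading it. No NLP beyond this is attempted — detecting
  an "expression of despair" in free text is out of scope, and lexicon
  quality is the deploying system's responsibility.
* Questionnaire gating is on by default: a questionnaire total that arrives
  before any step-1 signal is recorded in the decision trace as a gating
  violation and ignored, because soliciting a risk questionnaire (suicidal
  ideation in particular) can itself do harm when unprompted.

The engine is deliberately risk-agnostic: per-risk escalation ("suicide
refers faster than sleep problems") is expressed entirely through profile
thresholds and k-of-n rules. No shipped threshold is clinically validated;
profiles are illustrative placeholders.

## Auto-referral (consent-gated state machine)

The workflow is a finite state machine over states {idle, risk-detected,
takeover, caregiver-in-control, crisis-alerted, awaiting-self-contact,
caregiver-outreach, closed}. Consent is checked first and is absolute: a
referral on a case without prior consent emits `refuse_no_consent` and
closes — surfacing the blocked referral rather than silently dropping it,
so the deploying system can report that a risk was detected but
auto-referral was not authorised. (Referral *despite* missing consent, for
risks where safety might override autonomy, is deliberately not modelled.)

Branches after the consent gate: direct caregiver takeover when available;
otherwise a crisis branch that atomically emits the caregiver alert, the
expected-response-time message, the caregiver's contact details, and
short-term coping options; otherwise a non-crisis branch that asks the
patient to self-contact, provides the contact details, and notifies the
caregiver as a safety net. Contact details are emitted in *both* branches
so the patient knows whom to reach even if the system or network fails.

Time is explicit `tick(duration)` events, never a wall clock, so every run
is a pure function of (case, event sequence) and can be replayed bit-for-bit.
The self-contact deadline comparison is strict (`clock > deadline`), and
caregiver outreach fires at most once. Illegal events are rejected with a
diagnostic and leave the state unchanged, which makes replaying noisy logs
total. These properties are verified by exhaustive breadth-first
enumeration of all event sequences up to length 8 over all 8 combinations
of consent x step-in x crisis, de-duplicating states by signature (sound
because the step function is pure).

## Motivate-to-self-refer (situation grid and dialogue policy)

The user's situation is a cell in a 3x3 grid of initial stance towards
seeking human care (negative/doubting/positive) x situation severity
(low/medium/high). Following social-judgement theory, cells map to three
latitude bands with one referral strategy each:

* accept care {3, 6, 9} — latitude of acceptance → **facilitate** (provide
  contact details; motivation is already high, so raising ability and
  providing a trigger suffices);
* care potential {1, 2, 5} — latitude of noncommitment → **persuade**
  (raise motivation with a message tailored to the user's stated concern,
  then continue to facilitation *by default*, because people tend to stay
  with a default option; only an explicit objection stops the handover);
* reject care {4, 7, 8} — latitude of rejection → **accept the rejection**
  (pushing would backfire; keep a standing offer of contact details so the
  door stays open).

Cell 1 (negative stance, high severity) is care potential, not reject care:
at high severity there is little to lose by attempting persuasion. Grid ids
are numbered row-major with severity rows high→low; the tested contract is
the three membership sets, not the numbering.

Concern personalisation covers money (an amount the user called
problematic), travel time (hours), and stigma (family/friends/boss).
Dialogue scripts are JSON data with placeholder templates and branch
labels; the engine validates and tests structure — turn ordering, the two
3-option manipulation-check elicitations, the optional tips block, branch
resolution, placeholder totality, and reachability of contact details in
every strategy — never wording. Objections are explicit branch choices
(multiple choice), not sentiment analysis. The shipped wording is synthetic
illustrative text and is expected to be replaced per deployment.

## Instruments

Outcomes are 7-point responses centred as `raw − 4`, giving scores in
−3..3 with 0 neutral; this is read as the 7-point interpretation of a
"between −3.5 and 3.5" transformed scale (the endpoint convention is not
decisive for any analysis, since only deviations from 0 are tested).
Feeling of being heard (FBH) is the mean of 7 centred items with no
imputation of missing items. The Insomnia Severity Index is scored as the
0–28 item total with the standard published bands 0–7 / 8–14 / 15–21 /
22–28 (the bands are configuration, as they are not part of the engine's
contract). Cronbach's alpha uses the variance-ratio formula
`k/(k−1)·(1 − Σ var(item)/var(total))` with sample variances; it is
undefined at zero total variance and this is an error, not a NaN.

## Synthetic trial generator

The generator emulates the evaluated 3x3x3 within-subject design:
160 participants x 3 scenario-chats, each chat one cell of the 9 situations
x 3 strategies crossing sampled uniformly without replacement per
participant. A `restricted` 21-cell mode (dropping non-facilitate
strategies in accept-care situations) exists because the evaluated design
is reported inconsistently as both 27 and 21 combinations; the default is
the full crossing, which is what the reported degrees of freedom imply.
How the three scenarios per participant were constrained is not reported;
uniform sampling without replacement is used and configurable.

Outcome model: centred outcome = grand mean + situation effect + strategy
effect [+ interaction] [+ gender shift, FBH only] + participant intercept
+ residual, discretised by half-to-even rounding and clamping to −3..3.
FBH is generated as 7 items sharing a scenario-level latent plus item
noise, so the multi-item scale has realistic internal consistency.

Defaults and where they come from:

* counts and distributions reported for the evaluated sample: n = 160,
  3 chats; concerns 128/15/17 (money/time/stigma); gender 91/67/2
  (female/male/other); age mean 36, SD 10.41; ISI mean 17, SD 6.53; grand
  means ISR 0.76, ICAA −0.03, FBH 0.79. (Count fractions are used rather
  than the published rounded percentages, which do not sum to 1.)
* `sigma_participant = 1.0`, `sigma_residual = 1.4`: not reported; chosen
  so total outcome SD ≈ 1.7, matching the reported outcome SDs
  (1.85/1.98/1.66), with an intraclass correlation of ≈ 0.34, a typical
  value for repeated subjective ratings.
* `manipulation_fidelity = 0.68`: the probability a respondent reports the
  scripted severity/stance level. Not reported directly; calibrated once so
  that the synthetic manipulation check reproduces the reported large
  effect sizes (w ≈ 0.55/0.62).
* `fbh_item_sigma = 1.0`: calibrated once so the 7-item FBH scale's
  Cronbach's alpha falls in the reported 0.93–0.97 range (it lands at
  ≈ 0.95).
* Default situation effects are additive stance/severity gradients and
  strategy effects are moderate sum-to-zero vectors oriented the way the
  evaluation found (persuasion raising ISR most, etc.); they are
  illustrative magnitudes, not estimates of the original effects. The
  zero-effect model used for calibration testing sets all means and effects
  to zero while keeping the variance components.

What the generator does **not** emulate: recruitment and exclusion
(229 → 160 is not simulated; n is set directly), free-text chat content,
dropout, attention checks, floor/ceiling-induced skew beyond what
round-and-clamp produces, or any dependence of outcomes on the concern.
Passing tests on this generator therefore show that the *pipeline* is
correct and calibrated under its assumed data-generating process — not
that the original study's numbers would replicate on new human data.

## Inference

All Gaussian models are random-intercept linear mixed models estimated by
maximum likelihood (never REML: every reported comparison is an LRT on
fixed effects, and REML log-likelihoods are not comparable across fixed
structures; ML variance components are therefore slightly biased low, which
is documented rather than corrected). Fitting is delegated to
`statsmodels.MixedLM` with a tightened gradient tolerance; tests verify it
against the closed-form balanced-design ML estimators and a direct
evaluation of the per-group marginal Gaussian likelihood to 1e-6.
Likelihood-ratio tests report chi2 = 2·(ll1 − ll0) clipped at zero, df =
parameter-count difference, and the chi-square upper tail; fits must share
identical data rows (checked by fingerprint) and be nested (checked on the
term sets). Categorical terms are dummy-coded against the first observed
level; LRTs are invariant to this coding. Design matrices are rank-checked
term by term and a singular term is reported by name.

The manipulation check is a cumulative-logit (proportional-odds) model
with participant random intercept, written in-house because no installed
Python package fits random-intercept ordinal models. The random intercept
is integrated out with Gauss–Hermite quadrature (15 nodes by default;
thresholds are parametrised as (a, a + e^s) so ordering is structural, and
the scale parameter as e^t ≥ 0). The scripted level enters as a single
linear −1/0/1 predictor, giving the 1-df LRT the evaluation reports. With
zero clustering the model provably reduces to an ordinary cumulative-logit
fit, which is the test oracle (`statsmodels.OrderedModel`). Non-convergence
is flagged and warned, never silent; a derivative-free polish step handles
the occasional "precision loss" stop of BFGS near the optimum.

Effect size for chi-square tests is Cohen's w = sqrt(chi2/n). Pseudo-R2 is
reported in both McFadden and Nagelkerke forms because the variant used in
the original report is not identifiable; neither is asserted to reproduce
the published .14/.18.

The H3 test is a Wald F on the null-model intercept, F = (b/se)^2 on
(1, participants − 1) df. The original report's F(1, 318) denominator
cannot be derived from the stated models (160 participants x 3 chats); the
package reports its own naive df convention and flags the mismatch rather
than matching it. No multiple-testing correction is applied anywhere,
matching the original reporting of raw LRT p-values.

## Problem sizes and numerical choices

* Calibration is assessed at the design size (160 x 3) with 200 null
  replicates per ladder (binomial 99% interval at alpha = .05) and 100
  replicates per effect level for power; parameter recovery uses 200
  replicates. Recovery is judged against the generator's truth *on the
  observed scale* — the expected value of the rounded-and-clamped latent,
  computed in closed form — because discretisation attenuates latent
  effects by design.
* The scaled-down permutation null for the ordinal model (40 permutations,
  60 participants) bounds the rejection count by the exact binomial tail
  rather than estimating a rate.
* Degenerate inputs fail loudly: empty subsets, constant covariates
  (excluded with a diagnostic), rank-deficient designs, zero-variance
  reliability, out-of-range item scores.

## Known limitations

* Nothing here is clinically validated; thresholds, lexicons and scripts
  are placeholders by design.
* The LRT reference distribution is asymptotic; at the smallest subset
  sizes (H3's ≈ 50–60 observations) the naive-df Wald test is only
  approximately calibrated, which the calibration test quantifies.
* The CLMM supports a single random intercept and 3-level outcomes — the
  only configuration the pipeline needs.
* The full human dataset of the original evaluation is an optional external
  input; its Table-level statistics are not reproducible from this
  repository alone, and the property-based checks above stand in for them.
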