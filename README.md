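# aemh-triage

Safety-protocol toolkit for **autonomous e-mental-health (AEMH) systems** —
software that delivers mental-health support without a human caregiver in
the loop, and therefore has to detect risk situations itself and hand users
back to human care safely. The package is for researchers and builders of
such systems (chatbots, virtual-agent coaches, web-based self-help) who
need the risk-management logic to be explicit, configurable and testable,
plus a simulation-and-analysis bench for evaluating referral strategies.

It implements three protocols as executable machinery:

1. **Risk detection** (`risk_detection`) — a two-step rule engine. Step 1
   flags that a risk *might* exist via lexicon screening of free text and
   risk-indicating answers to screening questions. Step 2 decides whether
   to refer: a questionnaire total `T` refers when `T ≥ τ` (configured
   threshold), else a duration/severity/progression rule refers when at
   least *k* of *n* factors are negative (default 2 of 3). Questionnaire
   items are gated behind a step-1 signal, since unprompted risk
   questionnaires can themselves do harm.
2. **Auto-referral** (`auto_referral`) — a consent-gated finite state
   machine with takeover, crisis and non-crisis branches, explicit-tick
   time, a strict self-contact deadline and at-most-once caregiver
   outreach. No caregiver-disclosing action is ever emitted without prior
   consent (verified exhaustively over all event sequences up to length 8).
3. **Motivate to self-refer** (`referral_motivation`) — classifies the
   user's situation on a 3×3 grid of stance on seeking care × severity,
   maps the grid's three latitude-of-acceptance bands to strategies
   (*facilitate* {3,6,9}, *persuade* {1,2,5}, *accept rejection* {4,7,8}),
   and renders the strategy as a scripted dialogue personalised to the
   user's concern (money / travel time / stigma), with facilitation as the
   default continuation unless the user actively objects.

Around these, `instruments` scores the outcome measures (7-point scales
centred as `raw − 4`, the Insomnia Severity Index, Cronbach's α),
`trial_simulator` generates synthetic 3×3×3 within-subject trial data
(160 participants × 3 scenario-chats, participant random intercepts), and
`inference` runs the analysis pipeline: random-intercept linear mixed
models fitted by ML and compared with likelihood-ratio tests

> χ² = 2(ℓ₁ − ℓ₀),  df = Δ#params,  w = √(χ²/N),

plus a cumulative-link mixed model (Gauss–Hermite quadrature) for the
ordinal manipulation checks. See `docs/methods.md` for models,
assumptions and parameter choices.

## Worked example

```python
from aemh_triage import run_policy, Concern

result = run_policy("doubting", "high",
                    Concern("money", money_problem_amount=60.0))
print(result["strategy"], result["situation"])
for turn in result["transcript"]:
    print(f"[{turn['turn']}] {turn['text']}")
```

prints (abridged):

```
persuade {'stance': 'doubting', 'severity': 'high', 'id': 2, 'sit_type': 'care_potential'}
[greeting] Hello, I'm glad you came to talk to me. ...
[severity_check] How severe would you rate your sleeping problems at the moment?
[stance_check] And how do you feel about seeing a human therapist for these problems?
[tips_offer] Would you like a few tips that can help with sleeping problems?
[tips] Try to keep a regular bedtime, ...
[strategy_entry] I understand that cost is on your mind. Many clinics have
    sliding-scale fees, and a first appointment often costs less than the
    $60 you mentioned. ...
[announce_facilitation] I'd like to give you the contact details of a sleep
    clinic ... I'll share them with you now, unless you'd rather I didn't.
[contact_details] You can reach the sleep clinic at the Sleep Clinic,
    0800-SLEEP (weekdays 9:00-17:00). ...
```

A doubting stance in a severe situation is cell 2 of the grid — *care
potential* — so the agent persuades (tailored to the money concern) and
then continues to facilitation because the user did not object. Passing
`user_events={"announce_facilitation": "object"}` stops the handover.

Simulating and analysing a trial:

```python
from aemh_triage import generate_trial, run_hypothesis_ladders, cohen_w

df = generate_trial(seed=1)                       # 480 scenario-chats
report = run_hypothesis_ladders(df, ("h2",))
print(report["h2"]["strategy"])                   # {'n': 141, 'chi2': 12.29, 'df': 2, 'p': 0.0021}
print(round(cohen_w(142.98, 477), 2))             # 0.55
```

The H2 ladder asks whether agent strategy shifts intention to self-refer in
the care-potential situations: here χ²₂ = 12.29 (p ≈ .002) on 141
scenario-chats, i.e. the persuade strategy moves the outcome. `cohen_w`
turns any of the pipeline's chi-square statistics into an effect size.

The same functionality is available from the shell:

```bash
triage detect --profile profile.yaml --session session.jsonl   # exit 0/10/20
triage refer --case case.json --events events.json
triage chat --stance doubting --severity high --concern money --amount 60
triage simulate --seed 1 --out trial.csv
triage analyze --data trial.csv --hypothesis h2
```

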