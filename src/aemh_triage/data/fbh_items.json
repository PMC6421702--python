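{
  "comment": "Synthetic placeholder wording for the 7-item feeling-of-being-heard scale (two patient-satisfaction items, two trust-in-clinician items, three agent-specific items). Scoring is item-content-agnostic; deployments replace these texts with their validated items.",
  "items": [
    "The agent listened carefully to what I told it.",
    "The agent took my situation seriously.",
    "I trust the agent to act in my best interest.",
    "I felt comfortable telling the agent about my problems.",
    "The agent understood what matters to me.",
    "The agent responded to what I actually said.",
    "I felt heard by the agent."
  ]
}
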