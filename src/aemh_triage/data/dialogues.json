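{
  "comment": "Default dialogue scripts for the three referral strategies. Wording is synthetic illustrative text written for this package; the engine's contract is the turn ordering and branching, and deployments are expected to replace these templates wholesale.",
  "concern_messages": {
    "money": "I understand that cost is on your mind. Many clinics have sliding-scale fees, and a first appointment often costs less than the {amount} you mentioned. Your sleep is worth that investment.",
    "time": "I understand travel time matters to you. A first appointment usually fits in a single visit, and {hours} hours of travel may save you many sleepless nights. Some therapists also offer video consultations.",
    "stigma": "I understand you are worried about what your {stigma_group} might think. Seeing a therapist is confidential: nobody, including your {stigma_group}, needs to know unless you choose to tell them."
  },
  "common_prefix": [
    {
      "id": "greeting",
      "speaker": "agent",
      "text": "Hello, I'm glad you came to talk to me. I'd like to ask you a few questions about how you are sleeping."
    },
    {
      "id": "severity_check",
      "speaker": "agent",
      "text": "How severe would you rate your sleeping problems at the moment?",
      "responses": {"low": "stance_check", "medium": "stance_check", "high": "stance_check"},
      "default": "medium",
      "role": "manipulation_check_severity"
    },
    {
      "id": "stance_check",
      "speaker": "agent",
      "text": "And how do you feel about seeing a human therapist for these problems?",
      "responses": {"negative": "tips_offer", "doubting": "tips_offer", "positive": "tips_offer"},
      "default": "doubting",
      "role": "manipulation_check_stance"
    },
    {
      "id": "tips_offer",
      "speaker": "agent",
      "text": "Would you like a few tips that can help with sleeping problems?",
      "responses": {"yes": "tips", "no": "strategy_entry"},
      "default": "yes"
    },
    {
      "id": "tips",
      "speaker": "agent",
      "text": "Try to keep a regular bedtime, avoid screens in the hour before sleep, and keep caffeine to the morning. Small changes can already help."
    }
  ],
  "strategies": {
    "facilitate": [
      {
        "id": "strategy_entry",
        "speaker": "agent",
        "text": "Since you are open to seeing someone, let me make that as easy as possible."
      },
      {
        "id": "contact_details",
        "speaker": "agent",
        "text": "You can reach the sleep clinic at {contact}. They can usually schedule a first appointment within a week. Would you like me to repeat any of this?",
        "role": "contact_details"
      }
    ],
    "persuade": [
      {
        "id": "strategy_entry",
        "speaker": "agent",
        "text": "{concern_message}",
        "role": "persuasion"
      },
      {
        "id": "announce_facilitation",
        "speaker": "agent",
        "text": "I'd like to give you the contact details of a sleep clinic so you can take the next step. I'll share them with you now, unless you'd rather I didn't.",
        "responses": {"continue": "contact_details", "object": "objection_close"},
        "default": "continue"
      },
      {
        "id": "contact_details",
        "speaker": "agent",
        "text": "You can reach the sleep clinic at {contact}. They can usually schedule a first appointment within a week.",
        "role": "contact_details",
        "next": "end"
      },
      {
        "id": "objection_close",
        "speaker": "agent",
        "text": "That's alright, I won't share them now. You can always come back to me if you change your mind.",
        "next": "end"
      }
    ],
    "accept_rejection": [
      {
        "id": "strategy_entry",
        "speaker": "agent",
        "text": "I hear you: seeing a human therapist is not something you want right now, and that is your choice to make. I'm glad you are talking to me about it.",
        "role": "acceptance"
      },
      {
        "id": "standing_offer",
        "speaker": "agent",
        "text": "If you ever change your mind, I can give you the contact details of a sleep clinic — just ask. Would you like them now?",
        "responses": {"no": "farewell", "request_contact": "contact_details"},
        "default": "no",
        "role": "standing_offer"
      },
      {
        "id": "contact_details",
        "speaker": "agent",
        "text": "Of course. You can reach the sleep clinic at {contact}.",
        "role": "contact_details",
        "next": "farewell"
      },
      {
        "id": "farewell",
        "speaker": "agent",
        "text": "Alright. Do come back and talk to me whenever you like, especially if things get worse.",
        "next": "end"
      }
    ]
  }
}
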