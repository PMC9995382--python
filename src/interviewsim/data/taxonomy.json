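[
  {
    "label": "invitation_broad",
    "code": 0,
    "category": "recommended",
    "description": "Open-ended, non-suggestive question eliciting free narrative."
  },
  {
    "label": "invitation_focus",
    "code": 1,
    "category": "recommended",
    "description": "Open-ended, non-suggestive question eliciting narrative about a focused topic."
  },
  {
    "label": "facilitator",
    "code": 2,
    "category": "recommended",
    "description": "Non-suggestive prompt encouraging further narrative about content already mentioned."
  },
  {
    "label": "directive",
    "code": 3,
    "category": "recommended",
    "description": "Question focusing attention on content the child already mentioned, for further explanation."
  },
  {
    "label": "clarification",
    "code": 4,
    "category": "recommended",
    "description": "Attempt to clarify what the child has said."
  },
  {
    "label": "option_posing",
    "code": 5,
    "category": "not_recommended",
    "description": "Closed question focusing attention on content not yet mentioned, without implying a specific answer."
  },
  {
    "label": "specific_suggestive",
    "code": 6,
    "category": "not_recommended",
    "description": "Question indicating the expected answer by assuming details the child has not mentioned."
  },
  {
    "label": "unspecific_suggestive",
    "code": 7,
    "category": "not_recommended",
    "description": "Question indicating the expected answer without assuming specific unmentioned details."
  },
  {
    "label": "repetition",
    "code": 8,
    "category": "not_recommended",
    "description": "Asking again what the interviewer has just asked."
  },
  {
    "label": "inappropriate_utterance",
    "code": 9,
    "category": "not_recommended",
    "description": "Question unsuited to eliciting correct information from children (multiple details at once, difficult words, unclear grammar, temporal reasoning, or fantasy prompts)."
  },
  {
    "label": "multiple_choice",
    "code": 10,
    "category": "not_recommended",
    "description": "Question forcing the child to choose among offered options."
  }
]
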