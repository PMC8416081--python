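{
  "comment": "Negation cue lexicon and scope configuration. A mention is negated when a cue ends within `window` characters before the mention start with no clause-boundary punctuation in between.",
  "cues": ["not", "never", "wont", "won't", "refuse", "quit", "gave up"],
  "window": 8,
  "clause_boundaries": ",.;:!?、，。；：！？"
}
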