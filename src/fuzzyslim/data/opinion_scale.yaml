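# Package-default 7-term linguistic scale for importance elicitation,
# as triangular fuzzy numbers on [0, 1].  This is a configurable default of
# the toolkit, not a published membership-function set: replace it with the
# scale actually shown to your panel.
terms:
  very low: [0.0, 0.0, 0.1]
  low: [0.0, 0.1, 0.3]
  medium low: [0.1, 0.3, 0.5]
  medium: [0.3, 0.5, 0.7]
  medium high: [0.5, 0.7, 0.9]
  high: [0.7, 0.9, 1.0]
  very high: [0.9, 1.0, 1.0]
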