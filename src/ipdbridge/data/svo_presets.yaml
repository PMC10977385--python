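# Social-value-orientation presets for the stochastic responder agents.
# alpha: weight on own reward; delta: weight on other's reward;
# rho: weight on |self - other| inequality; beta: inverse temperature.
individualistic:
  alpha: 1.096
  delta: 0.382
  rho: -2.512
  beta: 0.037
prosocial:
  alpha: 1.368
  delta: -0.644
  rho: -3.798
  beta: 0.045
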