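# MMI weight set: AIC criterion, common ("same") parametric baseline.
criterion: AIC
baseline_method: same
weights:
  EAR:
    UNSCEAR_L: 0.73
    UNSCEAR_LQ: 0.27
  ERR:
    UNSCEAR_L: 0.73
    UNSCEAR_LQ: 0.27
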