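# MMI weight set: BIC criterion, common ("same") parametric baseline.
criterion: BIC
baseline_method: same
weights:
  EAR:
    BEIR7: 1.0
  ERR:
    BEIR7: 0.95
    UNSCEAR_L: 0.05
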