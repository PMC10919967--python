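# MMI weight set: BIC criterion, each model's original baseline.
# Weight concentrates on the linear Grant model, which is why the
# BIC-original model average and the single Grant model give the same
# mean RADS estimates.
criterion: BIC
baseline_method: original
weights:
  EAR:
    GRANT_L: 0.97
    GRANT_LQ: 0.02
    PRESTON_L: 0.01
  ERR:
    GRANT_L: 0.99
    GRANT_LQ: 0.01
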