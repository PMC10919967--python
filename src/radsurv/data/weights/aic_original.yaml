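# MMI weight set: AIC criterion, each model's original baseline.
# One consistent sum-to-one reading of the published weight table; the
# typeset source does not fix every cell-to-column assignment, so these
# ship as editable configuration rather than hard-coded constants.
criterion: AIC
baseline_method: original
weights:
  EAR:
    BEIR7: 0.67
    GRANT_L: 0.09
    GRANT_LQ: 0.24
  ERR:
    BEIR7: 0.65
    GRANT_L: 0.08
    GRANT_LQ: 0.18
    INWORKS_L: 0.01
    INWORKS_LQ: 0.02
    UNSCEAR_L: 0.04
    UNSCEAR_LQ: 0.02
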