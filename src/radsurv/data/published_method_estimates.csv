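method,sex,mission,point,ci_low,ci_high
bic_original,male,lunar,0.46,0.37,0.59
aic_original,male,lunar,0.37,0.30,0.45
grant_original,male,lunar,0.46,0.37,0.60
bic_original,female,lunar,0.74,0.61,0.89
aic_original,female,lunar,0.55,0.46,0.68
grant_original,female,lunar,0.74,0.61,0.89
bic_original,male,mars,2.69,2.13,3.38
aic_original,male,mars,2.14,1.73,2.69
grant_original,male,mars,2.69,2.12,3.39
bic_original,female,mars,4.27,3.55,5.08
aic_original,female,mars,3.21,2.67,3.96
grant_original,female,mars,4.27,3.54,5.10
bic_same,male,lunar,0.43,0.34,0.52
aic_same,male,lunar,0.41,0.35,0.48
grant_same,male,lunar,0.42,0.33,0.52
bic_same,female,lunar,0.72,0.61,0.84
aic_same,female,lunar,0.67,0.60,0.76
grant_same,female,lunar,0.67,0.54,0.82
bic_same,male,mars,2.52,2.02,3.01
aic_same,male,mars,2.45,2.09,2.84
grant_same,male,mars,2.44,1.89,3.03
bic_same,female,mars,4.16,3.53,4.89
aic_same,female,mars,4.01,3.57,4.56
grant_same,female,mars,3.90,3.15,4.75
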