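# Six-predictor registry: raw-score encoding and homogenized decision
# threshold t_s of each software.  SIFT's raw threshold 0.05 becomes 0.95
# after the inverted-scale homogenization; the signed-class predictors
# report the probability of the called class with the sign carrying the
# class (percent scale for MutationTaster, unit scale for MLb-LDLr).
SIFT:
  encoding: inverted
  t_s: 0.95
  magnitude_scale: 1.0
  min_h: 0.0
  max_h: 1.0
PolyPhen-2:
  encoding: direct
  t_s: 0.5
  magnitude_scale: 1.0
  min_h: 0.0
  max_h: 1.0
MLb-LDLr:
  encoding: signed_class
  t_s: 0.5
  magnitude_scale: 1.0
  min_h: 0.0
  max_h: 1.0
MutationTaster:
  encoding: signed_class
  t_s: 0.5
  magnitude_scale: 100.0
  min_h: 0.0
  max_h: 1.0
REVEL:
  encoding: direct
  t_s: 0.5
  magnitude_scale: 1.0
  min_h: 0.0
  max_h: 1.0
VARITY:
  encoding: direct
  t_s: 0.5
  magnitude_scale: 1.0
  min_h: 0.0
  max_h: 1.0
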