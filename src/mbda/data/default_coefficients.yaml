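# Default scoring configuration.
#
# The combination weights, scale (10.53), offset (1), score bounds (1, 100),
# concentration exponent (1/10) and category machinery are the published
# constants of the algorithm. The per-component linear models below are
# illustrative placeholders with the documented structure (11 markers split
# across three components, concentrations entering to the power 1/10);
# fitted component coefficients are not available in machine-readable form.
# Replace this file with the output of `mbda train` to use fitted models.
panel: [TNFRI, IL6, VCAM1, EGF, VEGFA, YKL40, MMP1, MMP3, SAA, LEPTIN, RESISTIN, CRP]
exponent: 0.1
crp_unit: mg/L
components:
  PTJC28:
    intercept: -32.0
    coefficients:
      TNFRI: 3.0
      IL6: 2.2
      SAA: 1.6
      YKL40: 2.0
      EGF: 2.8
      VEGFA: 2.4
      LEPTIN: 1.8
  PSJC28:
    intercept: -30.0
    coefficients:
      TNFRI: 2.6
      IL6: 2.0
      SAA: 1.4
      YKL40: 1.8
      EGF: 2.4
      VEGFA: 2.2
      MMP1: 1.6
      MMP3: 1.7
  PPGA:
    intercept: -12.0
    coefficients:
      IL6: 1.0
      SAA: 0.7
      YKL40: 0.8
      VCAM1: 0.9
      EGF: 1.1
      LEPTIN: 0.8
      RESISTIN: 0.7
# 2x2 shrinkage over (PTJC28, PSJC28); predicted PGA and CRP are excluded.
shrinkage:
  - [0.75, 0.20]
  - [0.25, 0.70]
# DAS28-CRP(4)-analogous combination; w_pga applies to PPGA on the 0-10
# scale (0.014 per mm of a 0-100 VAS = 0.14 per unit on 0-10).
combination:
  w_tjc: 0.56
  w_sjc: 0.28
  w_crp: 0.36
  w_pga: 0.14
  constant: 0.96
scale: 10.53
offset: 1.0
score_min: 1
score_max: 100
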