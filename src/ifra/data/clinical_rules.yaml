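# Three-stratum comparator rules for the eight bedside scales, with
# literature-derived thresholds.  Boundary convention: low and high intervals
# are closed, medium is open (e.g. Mini-BESTest: low x >= 24, medium
# 11 < x < 24, high x <= 11).  Multi-stratum source instruments were
# consolidated to three strata by preserving the extremes.
# direction lower_is_riskier: threshold_a bounds low (x >= a), threshold_b
# bounds high (x <= b); mirrored for higher_is_riskier.
- scale: MB
  feature: MB
  direction: lower_is_riskier
  threshold_a: 24.0
  threshold_b: 11.0
  source: Mini-BESTest, consolidated from the published five-level grading
- scale: FIM total
  feature: FIM_total
  direction: lower_is_riskier
  threshold_a: 72.0
  threshold_b: 37.0
  source: Functional Independence Measure, total score
- scale: FIM motor
  feature: FIM_motor
  direction: lower_is_riskier
  threshold_a: 65.0
  threshold_b: 26.0
  source: Functional Independence Measure, motor domain
- scale: POMA-B
  feature: POMA_B
  direction: lower_is_riskier
  threshold_a: 14.0
  threshold_b: 7.0
  source: Performance Oriented Mobility Assessment, balance section
- scale: TUG TTD
  feature: TUG_TTD
  direction: higher_is_riskier
  threshold_a: 12.0
  threshold_b: 22.0
  source: Timed Up and Go total duration, seconds
- scale: FES-I
  feature: FES_I
  direction: higher_is_riskier
  threshold_a: 19.0
  threshold_b: 28.0
  source: Falls Efficacy Scale International
- scale: Conley
  feature: Conley
  direction: higher_is_riskier
  threshold_a: 2.0
  threshold_b: 7.0
  source: Conley fall-risk scale
- scale: 10 MWT
  feature: MWT_10
  direction: lower_is_riskier
  threshold_a: 1.0
  threshold_b: 0.6
  source: 10 m walking test, comfortable speed in m/s
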