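# Published test-cohort classification results for the eight clinical
# comparator scales: percentage of subjects per stratum, by fall status,
# for 22 non-fallers and 10 fallers.  These percentages are *inputs* used to
# reconstruct integer counts and re-run the exact association test.
n_nonfallers: 22
n_fallers: 10
scales:
  - scale: MB
    nonfaller_low: 27.3
    nonfaller_medium: 72.7
    nonfaller_high: 0.0
    faller_low: 10.0
    faller_medium: 70.0
    faller_high: 20.0
  - scale: FIM total
    nonfaller_low: 95.4
    nonfaller_medium: 4.6
    nonfaller_high: 0.0
    faller_low: 90.0
    faller_medium: 10.0
    faller_high: 0.0
  - scale: FIM motor
    nonfaller_low: 95.4
    nonfaller_medium: 4.6
    nonfaller_high: 0.0
    faller_low: 80.0
    faller_medium: 20.0
    faller_high: 0.0
  - scale: POMA-B
    nonfaller_low: 59.1
    nonfaller_medium: 40.9
    nonfaller_high: 0.0
    faller_low: 50.0
    faller_medium: 40.0
    faller_high: 10.0
  - scale: TUG TTD
    nonfaller_low: 45.4
    nonfaller_medium: 45.4
    nonfaller_high: 9.2
    faller_low: 20.0
    faller_medium: 60.0
    faller_high: 20.0
  - scale: FES-I
    nonfaller_low: 31.8
    nonfaller_medium: 40.9
    nonfaller_high: 27.3
    faller_low: 20.0
    faller_medium: 50.0
    faller_high: 30.0
  - scale: Conley
    nonfaller_low: 72.7
    nonfaller_medium: 27.3
    nonfaller_high: 0.0
    faller_low: 60.0
    faller_medium: 30.0
    faller_high: 10.0
  - scale: 10 MWT
    nonfaller_low: 68.1
    nonfaller_medium: 27.3
    nonfaller_high: 4.6
    faller_low: 50.0
    faller_medium: 20.0
    faller_high: 30.0
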