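# Per-resource score rules for miRNA-target predictions.
# Predicted resources pass records whose score satisfies the inclusive
# comparison; validated resources pass records flagged as strong-evidence
# validated and ignore scores.
sources:
  TargetScan:
    kind: predicted
    threshold: -0.15   # context score
    direction: le
  DIANA-microT-CDS:
    kind: predicted
    threshold: 0.85    # miTG score
    direction: ge
  miRDB:
    kind: predicted
    threshold: 80.0    # target score
    direction: ge
  miRanda:
    kind: predicted
    threshold: -1.2    # miRSV score
    direction: le
  miRmap:
    kind: predicted
    threshold: 90.0    # miRmap score
    direction: ge
  miRTarBase:
    kind: validated
  miRecords:
    kind: validated
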