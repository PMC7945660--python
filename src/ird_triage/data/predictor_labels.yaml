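# Mapping of each predictor's raw output labels onto the binary verdict
# vocabulary used by the consensus rule.  Labels are matched case-insensitively
# after replacing spaces with underscores; unlisted labels are treated as
# missing (with a warning).  Edit to taste — e.g. to count PolyPhen-2
# "possibly_damaging" as a damaging vote.
sift:
  deleterious: damaging
  deleterious_low_confidence: damaging
  tolerated: tolerated
  tolerated_low_confidence: tolerated
pph2_hdiv:
  probably_damaging: damaging
  possibly_damaging: tolerated
  benign: tolerated
pph2_hvar:
  probably_damaging: damaging
  possibly_damaging: tolerated
  benign: tolerated
mutation_taster:
  disease_causing: damaging
  disease_causing_automatic: damaging
  polymorphism: tolerated
  polymorphism_automatic: tolerated
mutation_assessor:
  high: damaging
  medium: damaging
  low: tolerated
  neutral: tolerated
fathmm:
  deleterious: damaging
  tolerated: tolerated
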