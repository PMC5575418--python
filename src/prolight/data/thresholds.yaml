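# Clinically-relevant-difference configuration.
#
# d_medium is the minimal *medium* clinically relevant difference per scale:
# the half-width of the amber band when a score is compared with a matched
# reference mean.  size_class_bounds are ordered |difference| cutoffs mapping
# a group mean difference to no / trivial / small / medium / large.
#
# Provenance: the published evidence-based interpretation guidelines for the
# EORTC QLQ-C30 give per-scale magnitude ranges; the values below are round
# defaults in the spirit of those guideline magnitudes and are meant to be
# EDITED to the guideline values a deployment adopts.  The single-item
# tingling score has no published guideline and reuses the generic symptom
# defaults.  HADS values are on the 0-21 scale (HADS traffic-light feedback
# itself uses the absolute 0-7 / 8-10 / >=11 cutoffs, not d_medium).
scales:
  physical_functioning:
    d_medium: 10
    size_class_bounds: [2, 5, 10, 15]
  emotional_functioning:
    d_medium: 10
    size_class_bounds: [2, 5, 10, 15]
  cognitive_functioning:
    d_medium: 10
    size_class_bounds: [2, 5, 10, 15]
  social_functioning:
    d_medium: 10
    size_class_bounds: [2, 5, 10, 15]
  global_qol:
    d_medium: 10
    size_class_bounds: [2, 5, 10, 15]
  fatigue:
    d_medium: 10
    size_class_bounds: [2, 5, 10, 15]
  tingling:
    d_medium: 10
    size_class_bounds: [2, 5, 10, 15]
  hads_anxiety:
    d_medium: 3
    size_class_bounds: [0.5, 1.5, 3, 5]
  hads_depression:
    d_medium: 3
    size_class_bounds: [0.5, 1.5, 3, 5]
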