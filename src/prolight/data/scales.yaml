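# Scale registry: the QLQ-C30 scales fed back to patients, the added
# single-item neuropathy symptom, and the two HADS subscales.
# EORTC items are coded 1-4 (global items 1-7); HADS items 0-3.
scales:
  - scale_id: physical_functioning
    instrument: EORTC
    polarity: higher_is_better
    transform: eortc_functioning
    items: [q01, q02, q03, q04, q05]
    response_min: 1
    response_max: 4
    score_min: 0
    score_max: 100
  - scale_id: emotional_functioning
    instrument: EORTC
    polarity: higher_is_better
    transform: eortc_functioning
    items: [q21, q22, q23, q24]
    response_min: 1
    response_max: 4
    score_min: 0
    score_max: 100
  - scale_id: cognitive_functioning
    instrument: EORTC
    polarity: higher_is_better
    transform: eortc_functioning
    items: [q20, q25]
    response_min: 1
    response_max: 4
    score_min: 0
    score_max: 100
  - scale_id: social_functioning
    instrument: EORTC
    polarity: higher_is_better
    transform: eortc_functioning
    items: [q26, q27]
    response_min: 1
    response_max: 4
    score_min: 0
    score_max: 100
  - scale_id: global_qol
    instrument: EORTC
    polarity: higher_is_better
    transform: eortc_global
    items: [q29, q30]
    response_min: 1
    response_max: 7
    score_min: 0
    score_max: 100
  - scale_id: fatigue
    instrument: EORTC
    polarity: higher_is_worse
    transform: eortc_symptom
    items: [q10, q12, q18]
    response_min: 1
    response_max: 4
    score_min: 0
    score_max: 100
  - scale_id: tingling
    instrument: EORTC
    polarity: higher_is_worse
    transform: eortc_symptom
    items: [tingling]
    response_min: 1
    response_max: 4
    score_min: 0
    score_max: 100
  - scale_id: hads_anxiety
    instrument: HADS
    polarity: higher_is_worse
    transform: hads_sum
    items: [hads01, hads03, hads05, hads07, hads09, hads11, hads13]
    response_min: 0
    response_max: 3
    score_min: 0
    score_max: 21
  - scale_id: hads_depression
    instrument: HADS
    polarity: higher_is_worse
    transform: hads_sum
    items: [hads02, hads04, hads06, hads08, hads10, hads12, hads14]
    response_min: 0
    response_max: 3
    score_min: 0
    score_max: 21
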