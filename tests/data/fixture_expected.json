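{
  "_comment": "Hand-enumerated expected values for fixture_coding.tsv (6 items, 2 raters, rater-intersection policy, top_k=5). Alpha values are exact fractions worked from the coincidence-matrix definition: ipc/composite = 46/57.",
  "ipc": {
    "n_items": 6,
    "percent_agreement": 83.33333333333333,
    "classification_capacity": 83.33333333333333,
    "unique_total": 4,
    "unique_valid": 4,
    "unique_rater_generated": 0,
    "content_overlap": 40.0,
    "content_overlap_topk": 40.0,
    "top_codes": [["R_B*S", 2], ["E_B/S", 1], ["R_P,S", 1], ["R_X", 1]],
    "unresolved_items": ["i4"],
    "alpha": 0.8070175438596491
  },
  "icf": {
    "n_items": 6,
    "percent_agreement": 100.0,
    "classification_capacity": 83.33333333333333,
    "unique_total": 6,
    "unique_valid": 5,
    "unique_rater_generated": 1,
    "content_overlap": 66.66666666666667,
    "content_overlap_topk": 66.66666666666667,
    "top_codes": [["d760", 3], ["b152", 2], ["b28013", 2], ["b4200", 1], ["d7100", 1]],
    "unresolved_items": [],
    "alpha": 1.0
  },
  "composite": {
    "n_items": 6,
    "percent_agreement": 83.33333333333333,
    "classification_capacity": 66.66666666666667,
    "unique_total": 4,
    "unique_valid": 3,
    "unique_rater_generated": 1,
    "content_overlap": 40.0,
    "content_overlap_topk": 40.0,
    "top_codes": [["R_B[b28013]*S[d760]", 2], ["E_B[b4200]/S[d7100]", 1], ["R_P[b152],S[d760]", 1], ["R_X[nd-gh]", 1]],
    "unresolved_items": ["i4"],
    "alpha": 0.8070175438596491
  }
}
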