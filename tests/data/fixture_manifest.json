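{
 "seed": 11,
 "total_rows": 1638,
 "counts": {
  "bassoon/rows_in": 634,
  "bassoon/rows_after_quality": 361,
  "psd95/rows_in": 636,
  "psd95/rows_after_quality": 455,
  "munc13/rows_in": 231,
  "munc13/rows_after_quality": 168,
  "cav2/rows_in": 137,
  "cav2/rows_after_quality": 75,
  "bassoon/rows_after_link": 265,
  "psd95/rows_after_link": 278,
  "munc13/rows_after_link": 119,
  "cav2/rows_after_link": 61,
  "bassoon/clusters_detected": 2,
  "bassoon/clusters_after_frame_filter": 1,
  "psd95/clusters_detected": 2,
  "psd95/clusters_after_frame_filter": 1,
  "synapses_candidate": 1,
  "synapses_accepted": 1,
  "munc13/nanoclusters": 3,
  "cav2/nanoclusters": 2,
  "classified/munc13": 3,
  "classified/cav2": 2
 }
}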