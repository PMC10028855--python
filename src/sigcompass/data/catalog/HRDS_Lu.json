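{
 "first_author": "Lu",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "HRDS_Lu",
 "reference_id": "68",
 "required_scale": "log",
 "topic": "Chromosomal instability",
 "tumor_types": [
  "ovarian cancer",
  "breast cancer"
 ]
}
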