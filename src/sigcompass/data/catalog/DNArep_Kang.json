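{
 "first_author": "Kang",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "DNArep_Kang",
 "reference_id": "69",
 "required_scale": "log",
 "topic": "Chromosomal instability",
 "tumor_types": [
  "serous ovarian cystadenocarcinoma"
 ]
}
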