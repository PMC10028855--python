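{
 "first_author": "Chen H",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "Autophagy_ChenH",
 "reference_id": "66",
 "required_scale": "log",
 "topic": "Autophagy activity",
 "tumor_types": [
  "cervical cancer"
 ]
}
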