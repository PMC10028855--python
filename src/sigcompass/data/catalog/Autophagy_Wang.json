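{
 "first_author": "Wang",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "Autophagy_Wang",
 "reference_id": "65",
 "required_scale": "fpkm",
 "topic": "Autophagy activity",
 "tumor_types": [
  "glioblastoma"
 ]
}
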