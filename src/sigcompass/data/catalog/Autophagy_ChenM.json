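{
 "first_author": "Chen M",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "Autophagy_ChenM",
 "reference_id": "64",
 "required_scale": "fpkm",
 "topic": "Autophagy activity",
 "tumor_types": [
  "clear cell renal cell carcinoma"
 ]
}
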