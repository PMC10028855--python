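{
 "first_author": "Du",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "PassON_Du",
 "reference_id": "81",
 "required_scale": "tpm",
 "topic": "Immune system status",
 "tumor_types": [
  "metastatic melanoma"
 ]
}
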