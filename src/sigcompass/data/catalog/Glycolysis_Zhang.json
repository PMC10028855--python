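{
 "first_author": "Zhang",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "Glycolysis_Zhang",
 "reference_id": "85",
 "required_scale": "fpkm",
 "topic": "Tumor metabolisms",
 "tumor_types": [
  "lung adenocarcinoma"
 ]
}
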