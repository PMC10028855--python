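{
 "first_author": "Liang",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "Ferroptosis_Liang",
 "reference_id": "74",
 "required_scale": "fpkm",
 "topic": "Ferroptosis activity",
 "tumor_types": [
  "hepatocellular carcinoma"
 ]
}
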