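{
 "first_author": "Liu",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "Ferroptosis_Liu",
 "reference_id": "75",
 "required_scale": "log",
 "topic": "Ferroptosis activity",
 "tumor_types": [
  "prostate cancer"
 ]
}
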