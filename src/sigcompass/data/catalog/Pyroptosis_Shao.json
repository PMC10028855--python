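{
 "first_author": "Shao",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "Pyroptosis_Shao",
 "reference_id": "88",
 "required_scale": "log",
 "topic": "Pyroptosis activity",
 "tumor_types": [
  "gastric cancer"
 ]
}
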