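{
 "first_author": "Hao",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "ImmunoScore_Hao",
 "reference_id": "77",
 "required_scale": "log",
 "topic": "Immune system status",
 "tumor_types": [
  "epithelial ovarian cancer"
 ]
}
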