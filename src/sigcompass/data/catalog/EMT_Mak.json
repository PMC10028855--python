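{
 "first_author": "Mak",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "up_down_diff",
 "name": "EMT_Mak",
 "reference_id": "70",
 "required_scale": "log",
 "topic": "Epithelial to mesenchymal transition rate",
 "tumor_types": [
  "pan-cancer"
 ]
}
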