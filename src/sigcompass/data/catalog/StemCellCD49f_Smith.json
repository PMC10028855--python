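{
 "first_author": "Smith",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "ssgsea",
 "name": "StemCellCD49f_Smith",
 "reference_id": "32",
 "required_scale": "log",
 "topic": "Stemness status",
 "tumor_types": [
  "prostate cancer"
 ]
}
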