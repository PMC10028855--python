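{
 "first_author": "Robertson",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "ssgsea",
 "name": "CIS_Robertson",
 "reference_id": "72",
 "required_scale": "log",
 "topic": "Tumor dissemination",
 "tumor_types": [
  "bladder cancer"
 ]
}
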