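{
 "first_author": "Shen",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "ssgsea",
 "name": "IPSOV",
 "reference_id": "83",
 "required_scale": "log",
 "topic": "Immune system status",
 "tumor_types": [
  "ovarian cancer"
 ]
}
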