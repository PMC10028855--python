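{
 "first_author": "Merlos-Suarez",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "ssgsea",
 "name": "ISC_MerlosSuarez",
 "reference_id": "91",
 "required_scale": "log",
 "topic": "Stemness status",
 "tumor_types": [
  "colorectal cancer"
 ]
}
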