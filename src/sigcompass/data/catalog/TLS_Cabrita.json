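{
 "first_author": "Cabrita",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "zscore_mean",
 "name": "TLS_Cabrita",
 "reference_id": "80",
 "required_scale": "log",
 "topic": "Immune system status",
 "tumor_types": [
  "melanoma"
 ]
}
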