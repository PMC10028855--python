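{
 "first_author": "Roh",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "ssgsea",
 "name": "ImmunoScore_Roh",
 "reference_id": "43",
 "required_scale": "log",
 "topic": "Immune system status",
 "tumor_types": [
  "pan-cancer"
 ]
}
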