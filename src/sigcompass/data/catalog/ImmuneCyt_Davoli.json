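{
 "first_author": "Davoli",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "zscore_mean",
 "name": "ImmuneCyt_Davoli",
 "reference_id": "39",
 "required_scale": "log",
 "topic": "Immune system status",
 "tumor_types": [
  "pan-cancer"
 ]
}
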