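{
 "first_author": "Yang",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "zscore_mean",
 "name": "MitoticIndex_Yang",
 "reference_id": "87",
 "required_scale": "log",
 "topic": "Mitotic rate",
 "tumor_types": [
  "pan-cancer"
 ]
}
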