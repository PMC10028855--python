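{
 "first_author": "Winterhoff",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "zscore_mean",
 "name": "platinumResistanceSign",
 "reference_id": "67",
 "required_scale": "counts",
 "topic": "Chemo resistance",
 "tumor_types": [
  "high grade serous ovarian cancer"
 ]
}
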