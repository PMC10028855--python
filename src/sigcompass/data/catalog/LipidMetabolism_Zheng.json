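{
 "first_author": "Zheng",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "LipidMetabolism_Zheng",
 "reference_id": "84",
 "required_scale": "fpkm",
 "topic": "Tumor metabolisms",
 "tumor_types": [
  "epithelial ovarian cancer"
 ]
}
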