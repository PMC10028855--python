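{
 "first_author": "Ye",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "Pyroptosis_Ye",
 "reference_id": "73",
 "required_scale": "fpkm",
 "topic": "Pyroptosis activity",
 "tumor_types": [
  "ovarian cancer"
 ]
}
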