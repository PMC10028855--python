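{
 "first_author": "Hugo",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "sequencing"
 ],
 "method": "ssgsea",
 "name": "IPRES_Hugo",
 "reference_id": "82",
 "required_scale": "log",
 "topic": "Immune system status",
 "tumor_types": [
  "metastatic melanoma"
 ]
}
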