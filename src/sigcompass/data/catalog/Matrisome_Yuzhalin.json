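{
 "first_author": "Yuzhalin",
 "genes": [],
 "genes_available": false,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "zscore_mean",
 "name": "Matrisome_Yuzhalin",
 "reference_id": "71",
 "required_scale": "log",
 "topic": "Extracellular matrix composition",
 "tumor_types": [
  "ovarian cystadenocarcinoma",
  "gastric adenocarcinoma",
  "colorectal adenocarcinoma",
  "lung adenocarcinoma"
 ]
}
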