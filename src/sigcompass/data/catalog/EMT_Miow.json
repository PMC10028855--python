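{
 "first_author": "Miow",
 "genes": [
  {
   "direction": "up",
   "symbol": "VIM"
  },
  {
   "direction": "up",
   "symbol": "ZEB1"
  },
  {
   "direction": "up",
   "symbol": "SNAI2"
  },
  {
   "direction": "up",
   "symbol": "TWIST1"
  },
  {
   "direction": "up",
   "symbol": "FN1"
  },
  {
   "direction": "up",
   "symbol": "CDH2"
  },
  {
   "direction": "up",
   "symbol": "MMP2"
  },
  {
   "direction": "down",
   "symbol": "CDH1"
  },
  {
   "direction": "down",
   "symbol": "EPCAM"
  },
  {
   "direction": "down",
   "symbol": "CLDN4"
  },
  {
   "direction": "down",
   "symbol": "CLDN7"
  },
  {
   "direction": "down",
   "symbol": "KRT8"
  },
  {
   "direction": "down",
   "symbol": "KRT18"
  },
  {
   "direction": "down",
   "symbol": "ESRP1"
  }
 ],
 "genes_available": true,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "up_down_diff",
 "name": "EMT_Miow",
 "reference_id": "31",
 "required_scale": "log",
 "topic": "Epithelial to mesenchymal transition rate",
 "tumor_types": [
  "ovarian cancer"
 ]
}
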