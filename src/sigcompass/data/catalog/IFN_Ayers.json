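{
 "first_author": "Ayers",
 "genes": [
  {
   "direction": "up",
   "symbol": "IFNG"
  },
  {
   "direction": "up",
   "symbol": "STAT1"
  },
  {
   "direction": "up",
   "symbol": "IDO1"
  },
  {
   "direction": "up",
   "symbol": "CXCL10"
  },
  {
   "direction": "up",
   "symbol": "CXCL9"
  },
  {
   "direction": "up",
   "symbol": "HLA-DRA"
  }
 ],
 "genes_available": true,
 "input_types": [
  "sequencing"
 ],
 "method": "zscore_mean",
 "name": "IFN_Ayers",
 "reference_id": "60",
 "required_scale": "log",
 "topic": "Immune system status",
 "tumor_types": [
  "pan-cancer"
 ]
}
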