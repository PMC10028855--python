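{
 "first_author": "Messina",
 "genes": [
  {
   "direction": "up",
   "symbol": "CCL2"
  },
  {
   "direction": "up",
   "symbol": "CCL3"
  },
  {
   "direction": "up",
   "symbol": "CCL4"
  },
  {
   "direction": "up",
   "symbol": "CCL5"
  },
  {
   "direction": "up",
   "symbol": "CCL8"
  },
  {
   "direction": "up",
   "symbol": "CCL18"
  },
  {
   "direction": "up",
   "symbol": "CCL19"
  },
  {
   "direction": "up",
   "symbol": "CCL21"
  },
  {
   "direction": "up",
   "symbol": "CXCL9"
  },
  {
   "direction": "up",
   "symbol": "CXCL10"
  },
  {
   "direction": "up",
   "symbol": "CXCL11"
  },
  {
   "direction": "up",
   "symbol": "CXCL13"
  }
 ],
 "genes_available": true,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "zscore_mean",
 "name": "Chemokines_Messina",
 "reference_id": "42",
 "required_scale": "log",
 "topic": "Immune system status",
 "tumor_types": [
  "pan-cancer"
 ]
}
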