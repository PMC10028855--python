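{
 "first_author": "Ayers",
 "genes": [
  {
   "direction": "up",
   "symbol": "CCL5"
  },
  {
   "direction": "up",
   "symbol": "CD27"
  },
  {
   "direction": "up",
   "symbol": "CD274"
  },
  {
   "direction": "up",
   "symbol": "CD276"
  },
  {
   "direction": "up",
   "symbol": "CD8A"
  },
  {
   "direction": "up",
   "symbol": "CMKLR1"
  },
  {
   "direction": "up",
   "symbol": "CXCL9"
  },
  {
   "direction": "up",
   "symbol": "CXCR6"
  },
  {
   "direction": "up",
   "symbol": "HLA-DQA1"
  },
  {
   "direction": "up",
   "symbol": "HLA-DRB1"
  },
  {
   "direction": "up",
   "symbol": "HLA-E"
  },
  {
   "direction": "up",
   "symbol": "IDO1"
  },
  {
   "direction": "up",
   "symbol": "LAG3"
  },
  {
   "direction": "up",
   "symbol": "NKG7"
  },
  {
   "direction": "up",
   "symbol": "PDCD1LG2"
  },
  {
   "direction": "up",
   "symbol": "PSMB10"
  },
  {
   "direction": "up",
   "symbol": "STAT1"
  },
  {
   "direction": "up",
   "symbol": "TIGIT"
  }
 ],
 "genes_available": true,
 "input_types": [
  "sequencing"
 ],
 "method": "zscore_mean",
 "name": "Tinflam_Ayers",
 "reference_id": "60",
 "required_scale": "log",
 "topic": "Immune system status",
 "tumor_types": [
  "pan-cancer"
 ]
}
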