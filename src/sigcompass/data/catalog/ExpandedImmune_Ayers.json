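{
 "first_author": "Ayers",
 "genes": [
  {
   "direction": "up",
   "symbol": "CD3D"
  },
  {
   "direction": "up",
   "symbol": "IDO1"
  },
  {
   "direction": "up",
   "symbol": "CIITA"
  },
  {
   "direction": "up",
   "symbol": "CD3E"
  },
  {
   "direction": "up",
   "symbol": "CCL5"
  },
  {
   "direction": "up",
   "symbol": "GZMK"
  },
  {
   "direction": "up",
   "symbol": "CD2"
  },
  {
   "direction": "up",
   "symbol": "HLA-DRA"
  },
  {
   "direction": "up",
   "symbol": "CXCL13"
  },
  {
   "direction": "up",
   "symbol": "IL2RG"
  },
  {
   "direction": "up",
   "symbol": "NKG7"
  },
  {
   "direction": "up",
   "symbol": "HLA-E"
  },
  {
   "direction": "up",
   "symbol": "CXCR6"
  },
  {
   "direction": "up",
   "symbol": "LAG3"
  },
  {
   "direction": "up",
   "symbol": "TAGAP"
  },
  {
   "direction": "up",
   "symbol": "CXCL10"
  },
  {
   "direction": "up",
   "symbol": "STAT1"
  },
  {
   "direction": "up",
   "symbol": "GZMB"
  }
 ],
 "genes_available": true,
 "input_types": [
  "sequencing"
 ],
 "method": "zscore_mean",
 "name": "ExpandedImmune_Ayers",
 "reference_id": "60",
 "required_scale": "log",
 "topic": "Immune system status",
 "tumor_types": [
  "pan-cancer"
 ]
}
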