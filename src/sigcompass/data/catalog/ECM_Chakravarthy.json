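{
 "first_author": "Chakravarthy",
 "genes": [
  {
   "direction": "up",
   "symbol": "COL11A1"
  },
  {
   "direction": "up",
   "symbol": "COL10A1"
  },
  {
   "direction": "up",
   "symbol": "COL5A2"
  },
  {
   "direction": "up",
   "symbol": "FN1"
  },
  {
   "direction": "up",
   "symbol": "LOXL2"
  },
  {
   "direction": "up",
   "symbol": "POSTN"
  },
  {
   "direction": "up",
   "symbol": "THBS2"
  },
  {
   "direction": "up",
   "symbol": "MMP11"
  },
  {
   "direction": "up",
   "symbol": "SPP1"
  },
  {
   "direction": "up",
   "symbol": "COMP"
  },
  {
   "direction": "up",
   "symbol": "CTHRC1"
  },
  {
   "direction": "up",
   "symbol": "SULF1"
  },
  {
   "direction": "down",
   "symbol": "DCN"
  },
  {
   "direction": "down",
   "symbol": "LUM"
  },
  {
   "direction": "down",
   "symbol": "CILP"
  },
  {
   "direction": "down",
   "symbol": "ABI3BP"
  },
  {
   "direction": "down",
   "symbol": "OGN"
  },
  {
   "direction": "down",
   "symbol": "FBLN5"
  },
  {
   "direction": "down",
   "symbol": "PI16"
  },
  {
   "direction": "down",
   "symbol": "SCARA5"
  },
  {
   "direction": "down",
   "symbol": "MFAP4"
  },
  {
   "direction": "down",
   "symbol": "GPM6B"
  }
 ],
 "genes_available": true,
 "input_types": [
  "sequencing"
 ],
 "method": "up_down_diff",
 "name": "ECM_Chakravarthy",
 "reference_id": "40",
 "required_scale": "log",
 "topic": "Extracellular matrix composition",
 "tumor_types": [
  "pan-cancer"
 ]
}
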