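{
 "first_author": "Cheng",
 "genes": [
  {
   "direction": "none",
   "symbol": "VIM"
  },
  {
   "direction": "none",
   "symbol": "FN1"
  },
  {
   "direction": "none",
   "symbol": "CDH2"
  },
  {
   "direction": "none",
   "symbol": "ZEB1"
  },
  {
   "direction": "none",
   "symbol": "ZEB2"
  },
  {
   "direction": "none",
   "symbol": "SNAI1"
  },
  {
   "direction": "none",
   "symbol": "SNAI2"
  },
  {
   "direction": "none",
   "symbol": "TWIST1"
  },
  {
   "direction": "none",
   "symbol": "TWIST2"
  },
  {
   "direction": "none",
   "symbol": "FOXC2"
  },
  {
   "direction": "none",
   "symbol": "MMP2"
  },
  {
   "direction": "none",
   "symbol": "MMP3"
  },
  {
   "direction": "none",
   "symbol": "MMP9"
  },
  {
   "direction": "none",
   "symbol": "ITGB6"
  },
  {
   "direction": "none",
   "symbol": "SPARC"
  },
  {
   "direction": "none",
   "symbol": "COL1A1"
  },
  {
   "direction": "none",
   "symbol": "COL1A2"
  },
  {
   "direction": "none",
   "symbol": "COL3A1"
  },
  {
   "direction": "none",
   "symbol": "COL5A1"
  },
  {
   "direction": "none",
   "symbol": "COL5A2"
  },
  {
   "direction": "none",
   "symbol": "COL6A3"
  },
  {
   "direction": "none",
   "symbol": "THBS1"
  },
  {
   "direction": "none",
   "symbol": "THBS2"
  },
  {
   "direction": "none",
   "symbol": "POSTN"
  },
  {
   "direction": "none",
   "symbol": "TNC"
  },
  {
   "direction": "none",
   "symbol": "FBN1"
  },
  {
   "direction": "none",
   "symbol": "LOX"
  },
  {
   "direction": "none",
   "symbol": "LOXL2"
  },
  {
   "direction": "none",
   "symbol": "PDGFRB"
  },
  {
   "direction": "none",
   "symbol": "TGFB1"
  },
  {
   "direction": "none",
   "symbol": "TGFB2"
  },
  {
   "direction": "none",
   "symbol": "TGFBR2"
  },
  {
   "direction": "none",
   "symbol": "SERPINE1"
  },
  {
   "direction": "none",
   "symbol": "TIMP1"
  },
  {
   "direction": "none",
   "symbol": "TIMP3"
  },
  {
   "direction": "none",
   "symbol": "CCN2"
  },
  {
   "direction": "none",
   "symbol": "CCN1"
  },
  {
   "direction": "none",
   "symbol": "FSTL1"
  },
  {
   "direction": "none",
   "symbol": "IGFBP3"
  },
  {
   "direction": "none",
   "symbol": "WNT5A"
  },
  {
   "direction": "none",
   "symbol": "WNT5B"
  },
  {
   "direction": "none",
   "symbol": "SFRP1"
  },
  {
   "direction": "none",
   "symbol": "SFRP4"
  },
  {
   "direction": "none",
   "symbol": "DKK1"
  },
  {
   "direction": "none",
   "symbol": "VCAN"
  },
  {
   "direction": "none",
   "symbol": "EMP3"
  },
  {
   "direction": "none",
   "symbol": "CALD1"
  },
  {
   "direction": "none",
   "symbol": "TAGLN"
  },
  {
   "direction": "none",
   "symbol": "MYL9"
  },
  {
   "direction": "none",
   "symbol": "ACTA2"
  },
  {
   "direction": "none",
   "symbol": "S100A4"
  }
 ],
 "genes_available": true,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "ssgsea",
 "name": "EMT_Cheng",
 "reference_id": "61",
 "required_scale": "log",
 "topic": "Epithelial to mesenchymal transition rate",
 "tumor_types": [
  "breast cancer"
 ]
}
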