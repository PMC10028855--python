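{
 "first_author": "Carter",
 "genes": [
  {
   "direction": "up",
   "symbol": "TPX2"
  },
  {
   "direction": "up",
   "symbol": "PRC1"
  },
  {
   "direction": "up",
   "symbol": "FOXM1"
  },
  {
   "direction": "up",
   "symbol": "CDK1"
  },
  {
   "direction": "up",
   "symbol": "TGIF2"
  },
  {
   "direction": "up",
   "symbol": "MCM2"
  },
  {
   "direction": "up",
   "symbol": "H2AZ1"
  },
  {
   "direction": "up",
   "symbol": "TOP2A"
  },
  {
   "direction": "up",
   "symbol": "PCNA"
  },
  {
   "direction": "up",
   "symbol": "UBE2C"
  },
  {
   "direction": "up",
   "symbol": "MELK"
  },
  {
   "direction": "up",
   "symbol": "TRIP13"
  },
  {
   "direction": "up",
   "symbol": "NCAPD2"
  },
  {
   "direction": "up",
   "symbol": "MCM7"
  },
  {
   "direction": "up",
   "symbol": "RNASEH2A"
  },
  {
   "direction": "up",
   "symbol": "RAD51AP1"
  },
  {
   "direction": "up",
   "symbol": "KIF20A"
  },
  {
   "direction": "up",
   "symbol": "CDC45"
  },
  {
   "direction": "up",
   "symbol": "MAD2L1"
  },
  {
   "direction": "up",
   "symbol": "ESPL1"
  },
  {
   "direction": "up",
   "symbol": "CCNB2"
  },
  {
   "direction": "up",
   "symbol": "FEN1"
  },
  {
   "direction": "up",
   "symbol": "TTK"
  },
  {
   "direction": "up",
   "symbol": "CCT5"
  },
  {
   "direction": "up",
   "symbol": "RFC4"
  },
  {
   "direction": "up",
   "symbol": "ATAD2"
  },
  {
   "direction": "up",
   "symbol": "CKAP5"
  },
  {
   "direction": "up",
   "symbol": "NUP205"
  },
  {
   "direction": "up",
   "symbol": "CDC20"
  },
  {
   "direction": "up",
   "symbol": "CKS2"
  },
  {
   "direction": "up",
   "symbol": "RRM2"
  },
  {
   "direction": "up",
   "symbol": "ELAVL1"
  },
  {
   "direction": "up",
   "symbol": "CCNB1"
  },
  {
   "direction": "up",
   "symbol": "RRM1"
  },
  {
   "direction": "up",
   "symbol": "AURKB"
  },
  {
   "direction": "up",
   "symbol": "MSH6"
  },
  {
   "direction": "up",
   "symbol": "EZH2"
  },
  {
   "direction": "up",
   "symbol": "CTPS1"
  },
  {
   "direction": "up",
   "symbol": "DKC1"
  },
  {
   "direction": "up",
   "symbol": "OIP5"
  },
  {
   "direction": "up",
   "symbol": "CDCA8"
  },
  {
   "direction": "up",
   "symbol": "PTTG1"
  },
  {
   "direction": "up",
   "symbol": "CEP55"
  },
  {
   "direction": "up",
   "symbol": "H2AX"
  },
  {
   "direction": "up",
   "symbol": "CMAS"
  },
  {
   "direction": "up",
   "symbol": "NCAPH"
  },
  {
   "direction": "up",
   "symbol": "MCM10"
  },
  {
   "direction": "up",
   "symbol": "LSM4"
  },
  {
   "direction": "up",
   "symbol": "MTCH2"
  },
  {
   "direction": "up",
   "symbol": "ASF1B"
  },
  {
   "direction": "up",
   "symbol": "ZWINT"
  },
  {
   "direction": "up",
   "symbol": "TOPBP1"
  },
  {
   "direction": "up",
   "symbol": "PIF1"
  },
  {
   "direction": "up",
   "symbol": "DLGAP5"
  },
  {
   "direction": "up",
   "symbol": "BUB1B"
  },
  {
   "direction": "up",
   "symbol": "NCAPG2"
  },
  {
   "direction": "up",
   "symbol": "STIL"
  },
  {
   "direction": "up",
   "symbol": "AURKA"
  },
  {
   "direction": "up",
   "symbol": "KIF4A"
  },
  {
   "direction": "up",
   "symbol": "CDC6"
  },
  {
   "direction": "up",
   "symbol": "EXO1"
  },
  {
   "direction": "up",
   "symbol": "TYMS"
  },
  {
   "direction": "up",
   "symbol": "GINS1"
  },
  {
   "direction": "up",
   "symbol": "TK1"
  },
  {
   "direction": "up",
   "symbol": "CDC7"
  },
  {
   "direction": "up",
   "symbol": "MCM3"
  },
  {
   "direction": "up",
   "symbol": "BIRC5"
  },
  {
   "direction": "up",
   "symbol": "NUSAP1"
  },
  {
   "direction": "up",
   "symbol": "KIF2C"
  },
  {
   "direction": "up",
   "symbol": "CENPF"
  }
 ],
 "genes_available": true,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "zscore_mean",
 "name": "CIN_Carter",
 "reference_id": "46",
 "required_scale": "log",
 "topic": "Chromosomal instability",
 "tumor_types": [
  "pan-cancer"
 ]
}
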