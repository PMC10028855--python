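{
 "first_author": "Buffa",
 "genes": [
  {
   "direction": "up",
   "symbol": "VEGFA"
  },
  {
   "direction": "up",
   "symbol": "SLC2A1"
  },
  {
   "direction": "up",
   "symbol": "PGAM1"
  },
  {
   "direction": "up",
   "symbol": "ENO1"
  },
  {
   "direction": "up",
   "symbol": "LDHA"
  },
  {
   "direction": "up",
   "symbol": "TPI1"
  },
  {
   "direction": "up",
   "symbol": "P4HA1"
  },
  {
   "direction": "up",
   "symbol": "MRPS17"
  },
  {
   "direction": "up",
   "symbol": "CDKN3"
  },
  {
   "direction": "up",
   "symbol": "ADM"
  },
  {
   "direction": "up",
   "symbol": "NDRG1"
  },
  {
   "direction": "up",
   "symbol": "TUBB6"
  },
  {
   "direction": "up",
   "symbol": "ALDOA"
  },
  {
   "direction": "up",
   "symbol": "MIF"
  },
  {
   "direction": "up",
   "symbol": "ACOT7"
  },
  {
   "direction": "up",
   "symbol": "MCTS1"
  },
  {
   "direction": "up",
   "symbol": "PSRC1"
  },
  {
   "direction": "up",
   "symbol": "PSMA7"
  },
  {
   "direction": "up",
   "symbol": "ANLN"
  },
  {
   "direction": "up",
   "symbol": "TUBA1B"
  },
  {
   "direction": "up",
   "symbol": "MAD2L2"
  },
  {
   "direction": "up",
   "symbol": "SLC25A32"
  },
  {
   "direction": "up",
   "symbol": "SHCBP1"
  },
  {
   "direction": "up",
   "symbol": "CTSL"
  },
  {
   "direction": "up",
   "symbol": "KIF20A"
  },
  {
   "direction": "up",
   "symbol": "POLR3K"
  },
  {
   "direction": "up",
   "symbol": "ESRP1"
  },
  {
   "direction": "up",
   "symbol": "CORO1C"
  },
  {
   "direction": "up",
   "symbol": "PGK1"
  },
  {
   "direction": "up",
   "symbol": "BNIP3"
  },
  {
   "direction": "up",
   "symbol": "PDK1"
  },
  {
   "direction": "up",
   "symbol": "AK2"
  },
  {
   "direction": "up",
   "symbol": "YKT6"
  },
  {
   "direction": "up",
   "symbol": "CA9"
  },
  {
   "direction": "up",
   "symbol": "HK2"
  },
  {
   "direction": "up",
   "symbol": "GPI"
  },
  {
   "direction": "up",
   "symbol": "MRPL13"
  },
  {
   "direction": "up",
   "symbol": "CHCHD2"
  },
  {
   "direction": "up",
   "symbol": "TMEM45A"
  },
  {
   "direction": "up",
   "symbol": "SEC61G"
  },
  {
   "direction": "up",
   "symbol": "DDIT4"
  },
  {
   "direction": "up",
   "symbol": "ANKRD37"
  },
  {
   "direction": "up",
   "symbol": "PFKP"
  },
  {
   "direction": "up",
   "symbol": "HILPDA"
  },
  {
   "direction": "up",
   "symbol": "VPS37B"
  },
  {
   "direction": "up",
   "symbol": "SLC16A1"
  },
  {
   "direction": "up",
   "symbol": "UTP11"
  },
  {
   "direction": "up",
   "symbol": "RBM38"
  },
  {
   "direction": "up",
   "symbol": "HIGD1A"
  },
  {
   "direction": "up",
   "symbol": "GAPDH"
  },
  {
   "direction": "up",
   "symbol": "ADORA2B"
  },
  {
   "direction": "up",
   "symbol": "LRRC42"
  }
 ],
 "genes_available": true,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "zscore_mean",
 "name": "Hypoxia_Buffa",
 "reference_id": "38",
 "required_scale": "log",
 "topic": "Hypoxia activity",
 "tumor_types": [
  "pan-cancer"
 ]
}
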