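{
 "centroids": {
  "genes": [
   "CXCL9",
   "CXCL10",
   "CXCL11",
   "CCL5",
   "GZMB",
   "PRF1",
   "MUC16",
   "MUC1",
   "SLPI",
   "KRT8",
   "TFF1",
   "TFF3",
   "MCM2",
   "PCNA",
   "CDC20",
   "TOP2A",
   "MKI67",
   "CCNE1",
   "FAP",
   "COL5A1",
   "POSTN",
   "THBS2",
   "VCAN",
   "ZEB1"
  ],
  "subtypes": [
   "IMR",
   "DIF",
   "PRO",
   "MES"
  ],
  "values": [
   [
    2.0,
    -0.5,
    -0.5,
    -0.5
   ],
   [
    2.05,
    -0.51,
    -0.51,
    -0.51
   ],
   [
    2.1,
    -0.52,
    -0.52,
    -0.52
   ],
   [
    2.15,
    -0.53,
    -0.53,
    -0.53
   ],
   [
    2.2,
    -0.54,
    -0.54,
    -0.54
   ],
   [
    2.25,
    -0.55,
    -0.55,
    -0.55
   ],
   [
    -0.5,
    2.0,
    -0.5,
    -0.5
   ],
   [
    -0.51,
    2.05,
    -0.51,
    -0.51
   ],
   [
    -0.52,
    2.1,
    -0.52,
    -0.52
   ],
   [
    -0.53,
    2.15,
    -0.53,
    -0.53
   ],
   [
    -0.54,
    2.2,
    -0.54,
    -0.54
   ],
   [
    -0.55,
    2.25,
    -0.55,
    -0.55
   ],
   [
    -0.5,
    -0.5,
    2.0,
    -0.5
   ],
   [
    -0.51,
    -0.51,
    2.05,
    -0.51
   ],
   [
    -0.52,
    -0.52,
    2.1,
    -0.52
   ],
   [
    -0.53,
    -0.53,
    2.15,
    -0.53
   ],
   [
    -0.54,
    -0.54,
    2.2,
    -0.54
   ],
   [
    -0.55,
    -0.55,
    2.25,
    -0.55
   ],
   [
    -0.5,
    -0.5,
    -0.5,
    2.0
   ],
   [
    -0.51,
    -0.51,
    -0.51,
    2.05
   ],
   [
    -0.52,
    -0.52,
    -0.52,
    2.1
   ],
   [
    -0.53,
    -0.53,
    -0.53,
    2.15
   ],
   [
    -0.54,
    -0.54,
    -0.54,
    2.2
   ],
   [
    -0.55,
    -0.55,
    -0.55,
    2.25
   ]
  ]
 },
 "first_author": "Chen",
 "genes": [
  {
   "direction": "none",
   "symbol": "CXCL9"
  },
  {
   "direction": "none",
   "symbol": "CXCL10"
  },
  {
   "direction": "none",
   "symbol": "CXCL11"
  },
  {
   "direction": "none",
   "symbol": "CCL5"
  },
  {
   "direction": "none",
   "symbol": "GZMB"
  },
  {
   "direction": "none",
   "symbol": "PRF1"
  },
  {
   "direction": "none",
   "symbol": "MUC16"
  },
  {
   "direction": "none",
   "symbol": "MUC1"
  },
  {
   "direction": "none",
   "symbol": "SLPI"
  },
  {
   "direction": "none",
   "symbol": "KRT8"
  },
  {
   "direction": "none",
   "symbol": "TFF1"
  },
  {
   "direction": "none",
   "symbol": "TFF3"
  },
  {
   "direction": "none",
   "symbol": "MCM2"
  },
  {
   "direction": "none",
   "symbol": "PCNA"
  },
  {
   "direction": "none",
   "symbol": "CDC20"
  },
  {
   "direction": "none",
   "symbol": "TOP2A"
  },
  {
   "direction": "none",
   "symbol": "MKI67"
  },
  {
   "direction": "none",
   "symbol": "CCNE1"
  },
  {
   "direction": "none",
   "symbol": "FAP"
  },
  {
   "direction": "none",
   "symbol": "COL5A1"
  },
  {
   "direction": "none",
   "symbol": "POSTN"
  },
  {
   "direction": "none",
   "symbol": "THBS2"
  },
  {
   "direction": "none",
   "symbol": "VCAN"
  },
  {
   "direction": "none",
   "symbol": "ZEB1"
  }
 ],
 "genes_available": true,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "consensus_centroid",
 "name": "ConsensusOV_Chen",
 "reference_id": "30",
 "required_scale": "log",
 "topic": "Tumor subtypes",
 "tumor_types": [
  "high-grade serous ovarian carcinoma"
 ]
}
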