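{
 "first_author": "Charoentong",
 "genes": [
  {
   "class_label": "MHC",
   "direction": "none",
   "sub_class": "HLA-A",
   "symbol": "HLA-A",
   "weight": 1.0
  },
  {
   "class_label": "MHC",
   "direction": "none",
   "sub_class": "HLA-B",
   "symbol": "HLA-B",
   "weight": 1.0
  },
  {
   "class_label": "MHC",
   "direction": "none",
   "sub_class": "HLA-C",
   "symbol": "HLA-C",
   "weight": 1.0
  },
  {
   "class_label": "MHC",
   "direction": "none",
   "sub_class": "HLA-DPA1",
   "symbol": "HLA-DPA1",
   "weight": 1.0
  },
  {
   "class_label": "MHC",
   "direction": "none",
   "sub_class": "HLA-DPB1",
   "symbol": "HLA-DPB1",
   "weight": 1.0
  },
  {
   "class_label": "MHC",
   "direction": "none",
   "sub_class": "HLA-E",
   "symbol": "HLA-E",
   "weight": 1.0
  },
  {
   "class_label": "MHC",
   "direction": "none",
   "sub_class": "HLA-F",
   "symbol": "HLA-F",
   "weight": 1.0
  },
  {
   "class_label": "MHC",
   "direction": "none",
   "sub_class": "B2M",
   "symbol": "B2M",
   "weight": 1.0
  },
  {
   "class_label": "MHC",
   "direction": "none",
   "sub_class": "TAP1",
   "symbol": "TAP1",
   "weight": 1.0
  },
  {
   "class_label": "MHC",
   "direction": "none",
   "sub_class": "TAP2",
   "symbol": "TAP2",
   "weight": 1.0
  },
  {
   "class_label": "CP",
   "direction": "none",
   "sub_class": "PDCD1",
   "symbol": "PDCD1",
   "weight": -1.0
  },
  {
   "class_label": "CP",
   "direction": "none",
   "sub_class": "CTLA4",
   "symbol": "CTLA4",
   "weight": -1.0
  },
  {
   "class_label": "CP",
   "direction": "none",
   "sub_class": "LAG3",
   "symbol": "LAG3",
   "weight": -1.0
  },
  {
   "class_label": "CP",
   "direction": "none",
   "sub_class": "HAVCR2",
   "symbol": "HAVCR2",
   "weight": -1.0
  },
  {
   "class_label": "CP",
   "direction": "none",
   "sub_class": "TIGIT",
   "symbol": "TIGIT",
   "weight": -1.0
  },
  {
   "class_label": "CP",
   "direction": "none",
   "sub_class": "CD274",
   "symbol": "CD274",
   "weight": -1.0
  },
  {
   "class_label": "CP",
   "direction": "none",
   "sub_class": "PDCD1LG2",
   "symbol": "PDCD1LG2",
   "weight": -1.0
  },
  {
   "class_label": "CP",
   "direction": "none",
   "sub_class": "IDO1",
   "symbol": "IDO1",
   "weight": -1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Act_CD4",
   "symbol": "TNFRSF9",
   "weight": 1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Act_CD4",
   "symbol": "ICOS",
   "weight": 1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Act_CD4",
   "symbol": "CD69",
   "weight": 1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Act_CD8",
   "symbol": "GZMA",
   "weight": 1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Act_CD8",
   "symbol": "GZMB",
   "weight": 1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Act_CD8",
   "symbol": "PRF1",
   "weight": 1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Tem_CD4",
   "symbol": "CCR5",
   "weight": 1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Tem_CD4",
   "symbol": "GZMK",
   "weight": 1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Tem_CD4",
   "symbol": "IL7R",
   "weight": 1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Tem_CD8",
   "symbol": "EOMES",
   "weight": 1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Tem_CD8",
   "symbol": "KLRG1",
   "weight": 1.0
  },
  {
   "class_label": "EC",
   "direction": "none",
   "sub_class": "Tem_CD8",
   "symbol": "CXCR3",
   "weight": 1.0
  },
  {
   "class_label": "SC",
   "direction": "none",
   "sub_class": "Treg",
   "symbol": "FOXP3",
   "weight": -1.0
  },
  {
   "class_label": "SC",
   "direction": "none",
   "sub_class": "Treg",
   "symbol": "IL2RA",
   "weight": -1.0
  },
  {
   "class_label": "SC",
   "direction": "none",
   "sub_class": "Treg",
   "symbol": "IKZF2",
   "weight": -1.0
  },
  {
   "class_label": "SC",
   "direction": "none",
   "sub_class": "Treg",
   "symbol": "CCR8",
   "weight": -1.0
  },
  {
   "class_label": "SC",
   "direction": "none",
   "sub_class": "MDSC",
   "symbol": "CD14",
   "weight": -1.0
  },
  {
   "class_label": "SC",
   "direction": "none",
   "sub_class": "MDSC",
   "symbol": "ITGAM",
   "weight": -1.0
  },
  {
   "class_label": "SC",
   "direction": "none",
   "sub_class": "MDSC",
   "symbol": "ARG1",
   "weight": -1.0
  },
  {
   "class_label": "SC",
   "direction": "none",
   "sub_class": "MDSC",
   "symbol": "S100A8",
   "weight": -1.0
  }
 ],
 "genes_available": true,
 "input_types": [
  "sequencing"
 ],
 "method": "ips_composite",
 "name": "IPS_Charoentong",
 "reference_id": "78",
 "required_scale": "log",
 "topic": "Immune system status",
 "tumor_types": [
  "pan-cancer"
 ]
}
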