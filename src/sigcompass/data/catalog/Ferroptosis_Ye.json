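{
 "first_author": "Ye",
 "genes": [
  {
   "direction": "none",
   "symbol": "SLC7A11",
   "weight": 0.41
  },
  {
   "direction": "none",
   "symbol": "GPX4",
   "weight": -0.28
  },
  {
   "direction": "none",
   "symbol": "ACSL4",
   "weight": 0.19
  },
  {
   "direction": "none",
   "symbol": "NOX1",
   "weight": 0.25
  },
  {
   "direction": "none",
   "symbol": "FANCD2",
   "weight": 0.33
  },
  {
   "direction": "none",
   "symbol": "CISD1",
   "weight": -0.15
  },
  {
   "direction": "none",
   "symbol": "NFE2L2",
   "weight": -0.22
  },
  {
   "direction": "none",
   "symbol": "CARS1",
   "weight": 0.18
  },
  {
   "direction": "none",
   "symbol": "HSPB1",
   "weight": -0.12
  },
  {
   "direction": "none",
   "symbol": "ALOX12",
   "weight": -0.32
  }
 ],
 "genes_available": true,
 "input_types": [
  "microarray",
  "sequencing"
 ],
 "method": "weighted_sum",
 "name": "Ferroptosis_Ye",
 "reference_id": "73",
 "required_scale": "log",
 "topic": "Ferroptosis activity",
 "tumor_types": [
  "ovarian cancer"
 ]
}
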