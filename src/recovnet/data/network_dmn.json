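{
 "name": "dmn",
 "nodes": [
  {
   "id": "L_PCC_1",
   "hemisphere": "L",
   "region": "PCC"
  },
  {
   "id": "R_PCC_1",
   "hemisphere": "R",
   "region": "PCC"
  },
  {
   "id": "L_vmPFC_1",
   "hemisphere": "L",
   "region": "vmPFC"
  },
  {
   "id": "R_vmPFC_1",
   "hemisphere": "R",
   "region": "vmPFC"
  },
  {
   "id": "L_TPJ_1",
   "hemisphere": "L",
   "region": "TPJ"
  },
  {
   "id": "R_TPJ_1",
   "hemisphere": "R",
   "region": "TPJ"
  }
 ]
}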