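{
 "name": "co_fp",
 "nodes": [
  {
   "id": "M_dACC_msFC",
   "hemisphere": "midline",
   "region": "dACC_msFC",
   "subnetwork": "CO"
  },
  {
   "id": "L_aI_fO_1",
   "hemisphere": "L",
   "region": "aI_fO",
   "subnetwork": "CO"
  },
  {
   "id": "R_aI_fO_1",
   "hemisphere": "R",
   "region": "aI_fO",
   "subnetwork": "CO"
  },
  {
   "id": "L_aPFC_1",
   "hemisphere": "L",
   "region": "aPFC",
   "subnetwork": "CO"
  },
  {
   "id": "R_aPFC_1",
   "hemisphere": "R",
   "region": "aPFC",
   "subnetwork": "CO"
  },
  {
   "id": "L_thalamus_1",
   "hemisphere": "L",
   "region": "thalamus",
   "subnetwork": "CO"
  },
  {
   "id": "R_thalamus_1",
   "hemisphere": "R",
   "region": "thalamus",
   "subnetwork": "CO"
  },
  {
   "id": "L_dlPFC_1",
   "hemisphere": "L",
   "region": "dlPFC",
   "subnetwork": "FP"
  },
  {
   "id": "R_dlPFC_1",
   "hemisphere": "R",
   "region": "dlPFC",
   "subnetwork": "FP"
  },
  {
   "id": "L_IPL_1",
   "hemisphere": "L",
   "region": "IPL",
   "subnetwork": "FP"
  },
  {
   "id": "R_IPL_1",
   "hemisphere": "R",
   "region": "IPL",
   "subnetwork": "FP"
  },
  {
   "id": "L_IPS_1",
   "hemisphere": "L",
   "region": "IPS",
   "subnetwork": "FP"
  },
  {
   "id": "R_IPS_1",
   "hemisphere": "R",
   "region": "IPS",
   "subnetwork": "FP"
  },
  {
   "id": "L_IFG_1",
   "hemisphere": "L",
   "region": "IFG",
   "subnetwork": "FP"
  },
  {
   "id": "R_IFG_1",
   "hemisphere": "R",
   "region": "IFG",
   "subnetwork": "FP"
  },
  {
   "id": "L_precuneus_1",
   "hemisphere": "L",
   "region": "precuneus",
   "subnetwork": "FP"
  },
  {
   "id": "R_precuneus_1",
   "hemisphere": "R",
   "region": "precuneus",
   "subnetwork": "FP"
  },
  {
   "id": "M_mCC",
   "hemisphere": "midline",
   "region": "mCC",
   "subnetwork": "FP"
  }
 ]
}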