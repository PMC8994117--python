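{
 "name": "language",
 "nodes": [
  {
   "id": "L_IFG_1",
   "hemisphere": "L",
   "region": "IFG"
  },
  {
   "id": "L_IFG_2",
   "hemisphere": "L",
   "region": "IFG"
  },
  {
   "id": "L_IFG_3",
   "hemisphere": "L",
   "region": "IFG"
  },
  {
   "id": "L_IFG_4",
   "hemisphere": "L",
   "region": "IFG"
  },
  {
   "id": "L_IFG_5",
   "hemisphere": "L",
   "region": "IFG"
  },
  {
   "id": "L_MFG_1",
   "hemisphere": "L",
   "region": "MFG"
  },
  {
   "id": "L_MFG_2",
   "hemisphere": "L",
   "region": "MFG"
  },
  {
   "id": "L_MFG_3",
   "hemisphere": "L",
   "region": "MFG"
  },
  {
   "id": "L_MFG_4",
   "hemisphere": "L",
   "region": "MFG"
  },
  {
   "id": "L_SFG_1",
   "hemisphere": "L",
   "region": "SFG"
  },
  {
   "id": "L_SFG_2",
   "hemisphere": "L",
   "region": "SFG"
  },
  {
   "id": "L_SFG_3",
   "hemisphere": "L",
   "region": "SFG"
  },
  {
   "id": "L_SFG_4",
   "hemisphere": "L",
   "region": "SFG"
  },
  {
   "id": "L_PrG_1",
   "hemisphere": "L",
   "region": "PrG"
  },
  {
   "id": "L_PrG_2",
   "hemisphere": "L",
   "region": "PrG"
  },
  {
   "id": "L_PrG_3",
   "hemisphere": "L",
   "region": "PrG"
  },
  {
   "id": "L_PrG_4",
   "hemisphere": "L",
   "region": "PrG"
  },
  {
   "id": "L_PoG_1",
   "hemisphere": "L",
   "region": "PoG"
  },
  {
   "id": "L_PoG_2",
   "hemisphere": "L",
   "region": "PoG"
  },
  {
   "id": "L_IPL_1",
   "hemisphere": "L",
   "region": "IPL"
  },
  {
   "id": "L_IPL_2",
   "hemisphere": "L",
   "region": "IPL"
  },
  {
   "id": "L_IPL_3",
   "hemisphere": "L",
   "region": "IPL"
  },
  {
   "id": "L_IPL_4",
   "hemisphere": "L",
   "region": "IPL"
  },
  {
   "id": "L_STG_1",
   "hemisphere": "L",
   "region": "STG"
  },
  {
   "id": "L_STG_2",
   "hemisphere": "L",
   "region": "STG"
  },
  {
   "id": "L_STG_3",
   "hemisphere": "L",
   "region": "STG"
  },
  {
   "id": "L_STG_4",
   "hemisphere": "L",
   "region": "STG"
  },
  {
   "id": "L_STG_5",
   "hemisphere": "L",
   "region": "STG"
  },
  {
   "id": "L_MTG_1",
   "hemisphere": "L",
   "region": "MTG"
  },
  {
   "id": "L_MTG_2",
   "hemisphere": "L",
   "region": "MTG"
  },
  {
   "id": "L_MTG_3",
   "hemisphere": "L",
   "region": "MTG"
  },
  {
   "id": "L_MTG_4",
   "hemisphere": "L",
   "region": "MTG"
  },
  {
   "id": "L_ITG_1",
   "hemisphere": "L",
   "region": "ITG"
  },
  {
   "id": "L_ITG_2",
   "hemisphere": "L",
   "region": "ITG"
  },
  {
   "id": "R_IFG_1",
   "hemisphere": "R",
   "region": "IFG"
  },
  {
   "id": "R_IFG_2",
   "hemisphere": "R",
   "region": "IFG"
  },
  {
   "id": "R_IFG_3",
   "hemisphere": "R",
   "region": "IFG"
  },
  {
   "id": "R_IFG_4",
   "hemisphere": "R",
   "region": "IFG"
  },
  {
   "id": "R_IFG_5",
   "hemisphere": "R",
   "region": "IFG"
  },
  {
   "id": "R_MFG_1",
   "hemisphere": "R",
   "region": "MFG"
  },
  {
   "id": "R_MFG_2",
   "hemisphere": "R",
   "region": "MFG"
  },
  {
   "id": "R_MFG_3",
   "hemisphere": "R",
   "region": "MFG"
  },
  {
   "id": "R_MFG_4",
   "hemisphere": "R",
   "region": "MFG"
  },
  {
   "id": "R_SFG_1",
   "hemisphere": "R",
   "region": "SFG"
  },
  {
   "id": "R_SFG_2",
   "hemisphere": "R",
   "region": "SFG"
  },
  {
   "id": "R_SFG_3",
   "hemisphere": "R",
   "region": "SFG"
  },
  {
   "id": "R_SFG_4",
   "hemisphere": "R",
   "region": "SFG"
  },
  {
   "id": "R_PrG_1",
   "hemisphere": "R",
   "region": "PrG"
  },
  {
   "id": "R_PrG_2",
   "hemisphere": "R",
   "region": "PrG"
  },
  {
   "id": "R_PrG_3",
   "hemisphere": "R",
   "region": "PrG"
  },
  {
   "id": "R_PrG_4",
   "hemisphere": "R",
   "region": "PrG"
  },
  {
   "id": "R_PoG_1",
   "hemisphere": "R",
   "region": "PoG"
  },
  {
   "id": "R_PoG_2",
   "hemisphere": "R",
   "region": "PoG"
  },
  {
   "id": "R_IPL_1",
   "hemisphere": "R",
   "region": "IPL"
  },
  {
   "id": "R_IPL_2",
   "hemisphere": "R",
   "region": "IPL"
  },
  {
   "id": "R_IPL_3",
   "hemisphere": "R",
   "region": "IPL"
  },
  {
   "id": "R_IPL_4",
   "hemisphere": "R",
   "region": "IPL"
  },
  {
   "id": "R_STG_1",
   "hemisphere": "R",
   "region": "STG"
  },
  {
   "id": "R_STG_2",
   "hemisphere": "R",
   "region": "STG"
  },
  {
   "id": "R_STG_3",
   "hemisphere": "R",
   "region": "STG"
  },
  {
   "id": "R_STG_4",
   "hemisphere": "R",
   "region": "STG"
  },
  {
   "id": "R_STG_5",
   "hemisphere": "R",
   "region": "STG"
  },
  {
   "id": "R_MTG_1",
   "hemisphere": "R",
   "region": "MTG"
  },
  {
   "id": "R_MTG_2",
   "hemisphere": "R",
   "region": "MTG"
  },
  {
   "id": "R_MTG_3",
   "hemisphere": "R",
   "region": "MTG"
  },
  {
   "id": "R_MTG_4",
   "hemisphere": "R",
   "region": "MTG"
  },
  {
   "id": "R_ITG_1",
   "hemisphere": "R",
   "region": "ITG"
  },
  {
   "id": "R_ITG_2",
   "hemisphere": "R",
   "region": "ITG"
  }
 ]
}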