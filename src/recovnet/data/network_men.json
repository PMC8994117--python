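{
 "name": "men",
 "nodes": [
  {
   "id": "L_M1",
   "hemisphere": "L",
   "region": "M1"
  },
  {
   "id": "L_PMd_1",
   "hemisphere": "L",
   "region": "PMd"
  },
  {
   "id": "R_PMd_1",
   "hemisphere": "R",
   "region": "PMd"
  },
  {
   "id": "L_PMv_1",
   "hemisphere": "L",
   "region": "PMv"
  },
  {
   "id": "R_PMv_1",
   "hemisphere": "R",
   "region": "PMv"
  },
  {
   "id": "L_SPL_1",
   "hemisphere": "L",
   "region": "SPL"
  },
  {
   "id": "R_SPL_1",
   "hemisphere": "R",
   "region": "SPL"
  },
  {
   "id": "L_basal_ganglia_1",
   "hemisphere": "L",
   "region": "basal_ganglia"
  },
  {
   "id": "R_basal_ganglia_1",
   "hemisphere": "R",
   "region": "basal_ganglia"
  },
  {
   "id": "L_thalamus_1",
   "hemisphere": "L",
   "region": "thalamus"
  },
  {
   "id": "R_thalamus_1",
   "hemisphere": "R",
   "region": "thalamus"
  },
  {
   "id": "L_ant_inf_cerebellum_1",
   "hemisphere": "L",
   "region": "ant_inf_cerebellum"
  },
  {
   "id": "R_ant_inf_cerebellum_1",
   "hemisphere": "R",
   "region": "ant_inf_cerebellum"
  },
  {
   "id": "L_PoG_1",
   "hemisphere": "L",
   "region": "PoG"
  },
  {
   "id": "R_PoG_1",
   "hemisphere": "R",
   "region": "PoG"
  },
  {
   "id": "L_dentate_1",
   "hemisphere": "L",
   "region": "dentate"
  },
  {
   "id": "R_dentate_1",
   "hemisphere": "R",
   "region": "dentate"
  },
  {
   "id": "M_sup_cerebellum",
   "hemisphere": "midline",
   "region": "sup_cerebellum"
  }
 ]
}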