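{
 "pollutant": "PNC",
 "units": "particles/cm3",
 "scope": {
  "areas": [
   "Basel",
   "Geneva",
   "Lugano",
   "Wald"
  ],
  "radius_km": 20,
  "kind": "multi_area_indicator"
 },
 "intercept": 7805.0,
 "terms": [
  {
   "name": "Area_GE",
   "coef": 4270.0,
   "p": null,
   "direction": "either"
  },
  {
   "name": "Area_LU",
   "coef": 5895.0,
   "p": null,
   "direction": "either"
  },
  {
   "name": "Area_WA",
   "coef": 2388.0,
   "p": null,
   "direction": "either"
  },
  {
   "name": "TRAFLOAD_250",
   "coef": 0.00011,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "ROADLENGTH_100",
   "coef": 4.26,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "MAJROADLENGTH_50",
   "coef": 19.9,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "UGNL_1000",
   "coef": -0.00273,
   "p": null,
   "direction": "negative"
  }
 ],
 "stats": {
  "adj_r2": 0.85,
  "r2": 0.87,
  "rmse": 1991.0,
  "loocv_r2": 0.82,
  "loocv_rmse": 2255.0,
  "morans_i": -0.0663,
  "morans_i_p": 0.7059,
  "area_p": 1.0
 },
 "ranges": {},
 "truncation_exempt": [],
 "forced": [],
 "n_sites": 67,
 "flags": []
}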