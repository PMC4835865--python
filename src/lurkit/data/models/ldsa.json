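{
 "pollutant": "LDSA",
 "units": "um2/cm3",
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
 "intercept": 29.9,
 "terms": [
  {
   "name": "Area_GE",
   "coef": 9.17,
   "p": null,
   "direction": "either"
  },
  {
   "name": "Area_LU",
   "coef": 17.3,
   "p": null,
   "direction": "either"
  },
  {
   "name": "Area_WA",
   "coef": 0.502,
   "p": null,
   "direction": "either"
  },
  {
   "name": "MAJROADLENGTH_250",
   "coef": 0.00317,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "ROADLENGTH_100",
   "coef": 0.0094,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "TRAFNEAR",
   "coef": 0.000199,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "ALT",
   "coef": -0.0257,
   "p": null,
   "direction": "negative"
  }
 ],
 "stats": {
  "adj_r2": 0.89,
  "r2": 0.91,
  "rmse": 3.8,
  "loocv_r2": 0.87,
  "loocv_rmse": 4.2,
  "morans_i": -0.0434,
  "morans_i_p": 0.8349,
  "area_p": 1.0
 },
 "ranges": {},
 "truncation_exempt": [],
 "forced": [],
 "n_sites": 67,
 "flags": []
}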