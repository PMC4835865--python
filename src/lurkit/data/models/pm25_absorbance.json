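{
 "pollutant": "PM2.5_abs",
 "units": "1e-5/m",
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
 "intercept": 4.75,
 "terms": [
  {
   "name": "Area_GE",
   "coef": 0.559,
   "p": null,
   "direction": "either"
  },
  {
   "name": "Area_LU",
   "coef": 0.626,
   "p": null,
   "direction": "either"
  },
  {
   "name": "Area_WA",
   "coef": 0.369,
   "p": null,
   "direction": "either"
  },
  {
   "name": "MAJROADLENGTH_25",
   "coef": 0.00564,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "LOG_ALT",
   "coef": -0.715,
   "p": null,
   "direction": "negative"
  },
  {
   "name": "HEAVYTRAFLOAD_150",
   "coef": 1.08e-06,
   "p": null,
   "direction": "positive"
  }
 ],
 "stats": {
  "adj_r2": 0.79,
  "r2": 0.81,
  "rmse": 0.18,
  "loocv_r2": 0.77,
  "loocv_rmse": 0.19,
  "morans_i": 0.15,
  "morans_i_p": 0.1684,
  "area_p": 1.0
 },
 "ranges": {},
 "truncation_exempt": [],
 "forced": [],
 "n_sites": 74,
 "flags": []
}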