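{
 "pollutant": "NO2",
 "units": "ug/m3",
 "scope": {
  "areas": [
   "Payerne"
  ],
  "radius_km": 10,
  "kind": "area_specific"
 },
 "intercept": 44.0,
 "terms": [
  {
   "name": "BUILDINGS_50",
   "coef": 0.00289,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "TRAFLOAD_50",
   "coef": 1.26e-05,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "ALT",
   "coef": -0.0749,
   "p": null,
   "direction": "negative"
  }
 ],
 "stats": {
  "adj_r2": 0.61,
  "r2": 0.64,
  "rmse": 3.1,
  "loocv_r2": 0.49,
  "loocv_rmse": 3.6,
  "morans_i": 0.218,
  "morans_i_p": 0.0639
 },
 "ranges": {},
 "truncation_exempt": [],
 "forced": [],
 "n_sites": 40,
 "flags": []
}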