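{
 "pollutant": "NO2",
 "units": "ug/m3",
 "scope": {
  "areas": [
   "Montana"
  ],
  "radius_km": 10,
  "kind": "area_specific"
 },
 "intercept": 20.9,
 "terms": [
  {
   "name": "TRAFLOAD_25",
   "coef": 1.83e-05,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "LDRES_300",
   "coef": 3.15e-05,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "ALT",
   "coef": -0.0143,
   "p": null,
   "direction": "negative"
  },
  {
   "name": "BUILDINGS_1000",
   "coef": 2.4e-05,
   "p": null,
   "direction": "positive"
  }
 ],
 "stats": {
  "adj_r2": 0.46,
  "r2": 0.52,
  "rmse": 4.3,
  "loocv_r2": 0.39,
  "loocv_rmse": 4.6,
  "morans_i": 0.0414,
  "morans_i_p": 0.5248
 },
 "ranges": {},
 "truncation_exempt": [],
 "forced": [],
 "n_sites": 40,
 "flags": []
}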