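{
 "pollutant": "NO2",
 "units": "ug/m3",
 "scope": {
  "areas": [
   "Aarau"
  ],
  "radius_km": 10,
  "kind": "area_specific"
 },
 "intercept": 2.29,
 "terms": [
  {
   "name": "TRAFLOAD_25",
   "coef": 1.39e-05,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "BUILDINGS_75",
   "coef": 0.0012,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "INDUSTRY_5000",
   "coef": 3.32e-06,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "MAJROADLENGTH_500",
   "coef": 0.00179,
   "p": null,
   "direction": "positive"
  }
 ],
 "stats": {
  "adj_r2": 0.87,
  "r2": 0.88,
  "rmse": 2.7,
  "loocv_r2": 0.84,
  "loocv_rmse": 3.0,
  "morans_i": -0.149,
  "morans_i_p": 0.1524
 },
 "ranges": {},
 "truncation_exempt": [],
 "forced": [],
 "n_sites": 40,
 "flags": []
}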