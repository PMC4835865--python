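{
 "pollutant": "NO2",
 "units": "ug/m3",
 "scope": {
  "areas": [
   "Davos"
  ],
  "radius_km": 10,
  "kind": "area_specific"
 },
 "intercept": -6.19,
 "terms": [
  {
   "name": "TRAFLOAD_150",
   "coef": 6.04e-06,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "NO2_2010",
   "coef": 1.63,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "ROADLENGTH_50",
   "coef": 0.0552,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "BUILDINGS_25",
   "coef": 0.0102,
   "p": null,
   "direction": "positive"
  }
 ],
 "stats": {
  "adj_r2": 0.69,
  "r2": 0.73,
  "rmse": 6.1,
  "loocv_r2": 0.62,
  "loocv_rmse": 6.9,
  "morans_i": -0.296,
  "morans_i_p": 0.1211
 },
 "ranges": {},
 "truncation_exempt": [
  "NO2_2010"
 ],
 "forced": [],
 "n_sites": 38,
 "flags": []
}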