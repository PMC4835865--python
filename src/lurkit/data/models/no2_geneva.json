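{
 "pollutant": "NO2",
 "units": "ug/m3",
 "scope": {
  "areas": [
   "Geneva"
  ],
  "radius_km": 10,
  "kind": "area_specific"
 },
 "intercept": 14.2,
 "terms": [
  {
   "name": "POP_2000",
   "coef": 9.87e-05,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "MAJROADLENGTH_25",
   "coef": 0.234,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "HDRES_250",
   "coef": 6.19e-05,
   "p": null,
   "direction": "positive"
  }
 ],
 "stats": {
  "adj_r2": 0.49,
  "r2": 0.53,
  "rmse": 8.3,
  "loocv_r2": 0.43,
  "loocv_rmse": 8.9,
  "morans_i": -0.0393,
  "morans_i_p": 0.8908
 },
 "ranges": {},
 "truncation_exempt": [],
 "forced": [],
 "n_sites": 38,
 "flags": []
}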