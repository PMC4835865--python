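{
 "pollutant": "NO2",
 "units": "ug/m3",
 "scope": {
  "areas": [
   "Davos",
   "Montana"
  ],
  "altitude_band": ">=1000m",
  "kind": "alpine"
 },
 "intercept": 7.97,
 "terms": [
  {
   "name": "BUILDINGS_25",
   "coef": 0.0124,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "POP_500",
   "coef": 0.00658,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "TRAFNEAR",
   "coef": 0.000871,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "URBGREEN_2000",
   "coef": -4.97e-06,
   "p": null,
   "direction": "negative"
  }
 ],
 "stats": {
  "adj_r2": 0.5,
  "r2": 0.53,
  "rmse": 6.6,
  "loocv_r2": 0.46,
  "loocv_rmse": 7.0,
  "morans_i": 0.011,
  "morans_i_p": 0.8387,
  "area_p": 0.1593
 },
 "ranges": {},
 "truncation_exempt": [],
 "forced": [],
 "n_sites": 78,
 "flags": []
}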