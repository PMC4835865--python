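{
 "pollutant": "PM2.5",
 "units": "ug/m3",
 "scope": {
  "areas": [
   "Basel",
   "Geneva",
   "Lugano",
   "Wald"
  ],
  "kind": "multi_area"
 },
 "intercept": -13.2,
 "terms": [
  {
   "name": "PM25_2010",
   "coef": 1.81,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "MAJROADLENGTH_25",
   "coef": 0.0478,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "URBGREEN_5000",
   "coef": -5.21e-07,
   "p": null,
   "direction": "negative"
  },
  {
   "name": "TRAFMAJOR",
   "coef": 5.15e-05,
   "p": null,
   "direction": "positive"
  }
 ],
 "stats": {
  "adj_r2": 0.55,
  "r2": 0.57,
  "rmse": 2.0,
  "loocv_r2": 0.5,
  "loocv_rmse": 2.2,
  "morans_i": -0.0558,
  "morans_i_p": 0.7222,
  "area_p": 0.453
 },
 "ranges": {},
 "truncation_exempt": [
  "PM25_2010"
 ],
 "forced": [],
 "n_sites": 74,
 "flags": []
}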