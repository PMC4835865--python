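{
 "pollutant": "PMcoarse",
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
 "intercept": -0.69,
 "terms": [
  {
   "name": "PM10_2010",
   "coef": 0.337,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "TRAFMAJORLOAD_75",
   "coef": 4.13e-07,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "NATURAL_1000",
   "coef": -1.82e-06,
   "p": null,
   "direction": "negative"
  }
 ],
 "stats": {
  "adj_r2": 0.43,
  "r2": 0.45,
  "rmse": 1.5,
  "loocv_r2": 0.38,
  "loocv_rmse": 1.6,
  "morans_i": 0.125,
  "morans_i_p": 0.242,
  "area_p": 0.0551
 },
 "ranges": {},
 "truncation_exempt": [
  "PM10_2010"
 ],
 "forced": [],
 "n_sites": 74,
 "flags": []
}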