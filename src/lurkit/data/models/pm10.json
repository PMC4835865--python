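{
 "pollutant": "PM10",
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
 "intercept": -19.2,
 "terms": [
  {
   "name": "PM10_2010",
   "coef": 2.02,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "MAJROADLENGTH_25",
   "coef": 0.0707,
   "p": null,
   "direction": "positive"
  },
  {
   "name": "URBGREEN_5000",
   "coef": -9.2e-07,
   "p": null,
   "direction": "negative"
  }
 ],
 "stats": {
  "adj_r2": 0.62,
  "r2": 0.63,
  "rmse": 2.5,
  "loocv_r2": 0.59,
  "loocv_rmse": 2.6,
  "morans_i": 0.123,
  "morans_i_p": 0.2494,
  "area_p": 0.1012
 },
 "ranges": {},
 "truncation_exempt": [
  "PM10_2010"
 ],
 "forced": [],
 "n_sites": 74,
 "flags": []
}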