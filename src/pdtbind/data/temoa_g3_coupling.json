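{
 "label": "TEMOA-G3 host coupling",
 "role": "host-coupling",
 "modes": [
  {
   "weight": 0.000137,
   "b": 8.56e-07,
   "u0bar": -15.38,
   "sigma": 3.72,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 11.7
  },
  {
   "weight": 0.0348,
   "b": 1.52e-08,
   "u0bar": -6.58,
   "sigma": 4.51,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 48.7
  },
  {
   "weight": 0.965,
   "b": 2.62e-14,
   "u0bar": -11.87,
   "sigma": 4.8,
   "epsilon": 18.0,
   "u_tilde": 179.8,
   "n_l": 60.0
  }
 ]
}
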