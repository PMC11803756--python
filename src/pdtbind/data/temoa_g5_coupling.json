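{
 "label": "TEMOA-G5 host coupling",
 "role": "host-coupling",
 "modes": [
  {
   "weight": 2.82e-05,
   "b": 7.28e-09,
   "u0bar": -24.56,
   "sigma": 2.85,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 11.4
  },
  {
   "weight": 0.03,
   "b": 4.75e-09,
   "u0bar": -15.31,
   "sigma": 3.8,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 44.1
  },
  {
   "weight": 0.97,
   "b": 5.04e-28,
   "u0bar": 1.99,
   "sigma": 5.23,
   "epsilon": 12.9,
   "u_tilde": 123.8,
   "n_l": 60.0
  }
 ]
}
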