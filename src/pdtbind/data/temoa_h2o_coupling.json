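{
 "label": "TEMOA-H2O host coupling",
 "role": "host-coupling",
 "modes": [
  {
   "weight": 0.446,
   "b": 0.014,
   "u0bar": -0.51,
   "sigma": 2.66,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 3.0
  },
  {
   "weight": 0.554,
   "b": 0.00069,
   "u0bar": 0.0,
   "sigma": 3.12,
   "epsilon": 1.0,
   "u_tilde": 2.5,
   "n_l": 5.4
  }
 ]
}
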