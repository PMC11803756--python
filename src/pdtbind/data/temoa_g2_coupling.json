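{
 "label": "TEMOA-G2 host coupling",
 "role": "host-coupling",
 "modes": [
  {
   "weight": 0.0227,
   "b": 1.43e-08,
   "u0bar": -23.85,
   "sigma": 2.58,
   "epsilon": 2.1,
   "u_tilde": 2.1,
   "n_l": 7.4
  },
  {
   "weight": 0.199,
   "b": 1.49e-06,
   "u0bar": -15.95,
   "sigma": 3.17,
   "epsilon": 5.2,
   "u_tilde": 22.4,
   "n_l": 17.3
  },
  {
   "weight": 0.779,
   "b": 1.35e-06,
   "u0bar": -9.48,
   "sigma": 3.83,
   "epsilon": 9.0,
   "u_tilde": 89.8,
   "n_l": 46.3
  }
 ]
}
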