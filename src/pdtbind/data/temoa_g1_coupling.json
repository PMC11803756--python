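{
 "label": "TEMOA-G1 host coupling",
 "role": "host-coupling",
 "modes": [
  {
   "weight": 1.23e-05,
   "b": 2.71e-09,
   "u0bar": -19.14,
   "sigma": 3.72,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 15.9
  },
  {
   "weight": 0.0071,
   "b": 2.12e-18,
   "u0bar": -22.23,
   "sigma": 4.69,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 49.3
  },
  {
   "weight": 0.993,
   "b": 9.57e-13,
   "u0bar": -8.91,
   "sigma": 4.78,
   "epsilon": 20.0,
   "u_tilde": 200.0,
   "n_l": 60.0
  }
 ]
}
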