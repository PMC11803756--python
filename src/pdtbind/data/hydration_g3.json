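{
 "label": "G3 hydration",
 "role": "solvent-coupling",
 "modes": [
  {
   "weight": 2.98e-06,
   "b": 1.17e-09,
   "u0bar": -11.28,
   "sigma": 3.12,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 15.1
  },
  {
   "weight": 0.00557,
   "b": 2.98e-16,
   "u0bar": -10.69,
   "sigma": 4.44,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 33.5
  },
  {
   "weight": 0.994,
   "b": 1.57e-13,
   "u0bar": -4.38,
   "sigma": 4.05,
   "epsilon": 1.5,
   "u_tilde": 1.5,
   "n_l": 60.0
  }
 ]
}
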