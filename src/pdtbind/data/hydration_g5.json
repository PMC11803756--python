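{
 "label": "G5 hydration",
 "role": "solvent-coupling",
 "modes": [
  {
   "weight": 7.94e-08,
   "b": 3.68e-06,
   "u0bar": -5.86,
   "sigma": 3.99,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 9.2
  },
  {
   "weight": 0.0016,
   "b": 2.3e-16,
   "u0bar": -11.04,
   "sigma": 4.49,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 26.3
  },
  {
   "weight": 0.998,
   "b": 0.0,
   "u0bar": -10.4,
   "sigma": 4.47,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 56.9
  }
 ]
}
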