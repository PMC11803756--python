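{
 "label": "G2 hydration",
 "role": "solvent-coupling",
 "modes": [
  {
   "weight": 0.00127,
   "b": 4.6e-07,
   "u0bar": -6.87,
   "sigma": 3.37,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 13.4
  },
  {
   "weight": 0.999,
   "b": 2.41e-09,
   "u0bar": 3.9,
   "sigma": 4.45,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 36.2
  }
 ]
}
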