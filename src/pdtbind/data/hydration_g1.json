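{
 "label": "G1 hydration",
 "role": "solvent-coupling",
 "modes": [
  {
   "weight": 2.79e-05,
   "b": 2.2e-11,
   "u0bar": -7.51,
   "sigma": 4.27,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 26.2
  },
  {
   "weight": 0.999,
   "b": 3.2e-14,
   "u0bar": 13.42,
   "sigma": 6.27,
   "epsilon": 2.3,
   "u_tilde": 2.3,
   "n_l": 60.0
  }
 ]
}
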