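{
 "label": "G4 hydration",
 "role": "solvent-coupling",
 "modes": [
  {
   "weight": 8.64e-05,
   "b": 1.23e-09,
   "u0bar": -6.83,
   "sigma": 4.11,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 20.2
  },
  {
   "weight": 0.999,
   "b": 1.7e-12,
   "u0bar": 9.74,
   "sigma": 5.68,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 57.9
  }
 ]
}
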