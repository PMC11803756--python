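{
 "label": "H2O hydration",
 "role": "solvent-coupling",
 "modes": [
  {
   "weight": 1.0,
   "b": 0.00577,
   "u0bar": 2.41,
   "sigma": 3.46,
   "epsilon": 3.9,
   "u_tilde": 3.9,
   "n_l": 2.5
  }
 ]
}
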