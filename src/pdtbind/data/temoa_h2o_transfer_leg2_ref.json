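{
 "label": "TEMOA-H2O transfer, leg 2 (published fit)",
 "role": "transfer-unbinding",
 "modes": [
  {
   "weight": 0.418,
   "b": 0.0149,
   "u0bar": 17.1,
   "sigma": 4.36,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 2.95
  },
  {
   "weight": 0.582,
   "b": 0.00065,
   "u0bar": 17.7,
   "sigma": 4.66,
   "epsilon": 1.0,
   "u_tilde": 0.0,
   "n_l": 6.51
  }
 ]
}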