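{
 "label": "TEMOA-H2O transfer, leg 1 (published fit)",
 "role": "transfer-binding",
 "modes": [
  {
   "weight": 0.462,
   "b": 0.00582,
   "u0bar": 14.8,
   "sigma": 4.36,
   "epsilon": 3.65,
   "u_tilde": 4.34,
   "n_l": 2.5
  },
  {
   "weight": 0.538,
   "b": 0.00582,
   "u0bar": 18.8,
   "sigma": 4.66,
   "epsilon": 3.65,
   "u_tilde": 4.34,
   "n_l": 2.5
  }
 ]
}
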