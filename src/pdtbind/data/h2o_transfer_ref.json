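{
 "label": "water-in-water transfer (published fit)",
 "role": "transfer-binding",
 "modes": [
  {
   "weight": 1.0,
   "b": 0.00582,
   "u0bar": 20.1,
   "sigma": 4.89,
   "epsilon": 3.9,
   "u_tilde": 3.9,
   "n_l": 2.5
  }
 ]
}
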