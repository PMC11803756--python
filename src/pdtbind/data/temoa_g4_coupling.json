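{
 "label": "TEMOA-G4 host coupling",
 "role": "host-coupling",
 "modes": [
  {
   "weight": 3.9e-05,
   "b": 1.55e-09,
   "u0bar": -27.2,
   "sigma": 3.0,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 14.3
  },
  {
   "weight": 0.0307,
   "b": 3.29e-10,
   "u0bar": -20.79,
   "sigma": 3.54,
   "epsilon": 1.0,
   "u_tilde": 1.0,
   "n_l": 50.5
  },
  {
   "weight": 0.969,
   "b": 8.32e-11,
   "u0bar": -11.57,
   "sigma": 4.49,
   "epsilon": 18.8,
   "u_tilde": 188.0,
   "n_l": 60.0
  }
 ]
}
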