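{
 "units": "kcal/mol",
 "note": "excess free energies of the double-decoupling legs; DDM = host - solvent",
 "systems": {
  "TEMOA-H2O": {
   "host_coupling": -3.87,
   "solvent_coupling": -4.5,
   "ddm": 0.628,
   "atm": 0.845
  },
  "TEMOA-G1": {
   "host_coupling": -14.2,
   "solvent_coupling": -2.51,
   "ddm": -11.7,
   "atm": -10.5
  },
  "TEMOA-G2": {
   "host_coupling": -17.0,
   "solvent_coupling": -4.32,
   "ddm": -12.7,
   "atm": -12.7
  },
  "TEMOA-G3": {
   "host_coupling": -14.3,
   "solvent_coupling": -3.5,
   "ddm": -10.8,
   "atm": -11.6
  },
  "TEMOA-G4": {
   "host_coupling": -17.6,
   "solvent_coupling": -3.54,
   "ddm": -14.1,
   "atm": -13.9
  },
  "TEMOA-G5": {
   "host_coupling": -15.1,
   "solvent_coupling": -3.19,
   "ddm": -11.9,
   "atm": -11.7
  }
 }
}
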