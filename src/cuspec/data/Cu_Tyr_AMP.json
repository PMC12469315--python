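{
 "name": "Cu_Tyr_AMP",
 "pKw": 13.78,
 "temperature_C": 20.0,
 "ionic_strength_M": 0.1,
 "components": [
  {
   "id": "Cu",
   "name": "copper(II)",
   "role": "metal",
   "charge": 2
  },
  {
   "id": "Tyr",
   "name": "tyrosinate",
   "role": "ligand",
   "charge": -2
  },
  {
   "id": "AMP",
   "name": "adenosine-5'-monophosphate",
   "role": "ligand",
   "charge": -2
  },
  {
   "id": "H",
   "name": "proton",
   "role": "proton",
   "charge": 1
  }
 ],
 "species": [
  {
   "name": "H(Tyr)",
   "stoich": {
    "Tyr": 1,
    "H": 1
   },
   "log_beta": 10.28,
   "sigma": 0.02
  },
  {
   "name": "H2(Tyr)",
   "stoich": {
    "Tyr": 1,
    "H": 2
   },
   "log_beta": 19.29,
   "sigma": 0.02
  },
  {
   "name": "H3(Tyr)",
   "stoich": {
    "Tyr": 1,
    "H": 3
   },
   "log_beta": 21.81,
   "sigma": 0.03
  },
  {
   "name": "CuH2(Tyr)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "H": 2
   },
   "log_beta": 22.39,
   "sigma": 0.05
  },
  {
   "name": "CuH(Tyr)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "H": 1
   },
   "log_beta": 18.54,
   "sigma": 0.03
  },
  {
   "name": "CuH2(Tyr)2",
   "stoich": {
    "Cu": 1,
    "Tyr": 2,
    "H": 2
   },
   "log_beta": 35.38,
   "sigma": 0.03
  },
  {
   "name": "CuH(Tyr)2",
   "stoich": {
    "Cu": 1,
    "Tyr": 2,
    "H": 1
   },
   "log_beta": 25.99,
   "sigma": 0.03
  },
  {
   "name": "Cu(OH)2",
   "stoich": {
    "Cu": 1,
    "H": -2
   },
   "log_beta": -13.13,
   "sigma": null
  },
  {
   "name": "H(AMP)",
   "stoich": {
    "AMP": 1,
    "H": 1
   },
   "log_beta": 6.43,
   "sigma": 0.02
  },
  {
   "name": "H2(AMP)",
   "stoich": {
    "AMP": 1,
    "H": 2
   },
   "log_beta": 10.45,
   "sigma": 0.02
  },
  {
   "name": "Cu(AMP)",
   "stoich": {
    "Cu": 1,
    "AMP": 1
   },
   "log_beta": 3.02,
   "sigma": 0.08
  },
  {
   "name": "Cu(AMP)(OH)",
   "stoich": {
    "Cu": 1,
    "AMP": 1,
    "H": -1
   },
   "log_beta": -3.82,
   "sigma": 0.05
  },
  {
   "name": "Cu(Tyr)H3(AMP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "AMP": 1,
    "H": 3
   },
   "log_beta": 32.11,
   "sigma": 0.07
  },
  {
   "name": "Cu(Tyr)H2(AMP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "AMP": 1,
    "H": 2
   },
   "log_beta": 27.59,
   "sigma": 0.07
  },
  {
   "name": "Cu(Tyr)H(AMP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "AMP": 1,
    "H": 1
   },
   "log_beta": 22.14,
   "sigma": 0.03
  },
  {
   "name": "Cu(Tyr)(AMP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "AMP": 1
   },
   "log_beta": 14.87,
   "sigma": 0.04
  },
  {
   "name": "Cu(Tyr)(AMP)(OH)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "AMP": 1,
    "H": -1
   },
   "log_beta": 4.62,
   "sigma": 0.05
  }
 ]
}
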