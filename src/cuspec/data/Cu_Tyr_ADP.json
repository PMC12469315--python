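{
 "name": "Cu_Tyr_ADP",
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
   "id": "ADP",
   "name": "adenosine-5'-diphosphate",
   "role": "ligand",
   "charge": -3
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
   "name": "H(ADP)",
   "stoich": {
    "ADP": 1,
    "H": 1
   },
   "log_beta": 6.55,
   "sigma": 0.01
  },
  {
   "name": "H2(ADP)",
   "stoich": {
    "ADP": 1,
    "H": 2
   },
   "log_beta": 10.63,
   "sigma": 0.02
  },
  {
   "name": "CuH(ADP)",
   "stoich": {
    "Cu": 1,
    "ADP": 1,
    "H": 1
   },
   "log_beta": 10.84,
   "sigma": 0.03
  },
  {
   "name": "Cu(ADP)",
   "stoich": {
    "Cu": 1,
    "ADP": 1
   },
   "log_beta": 6.99,
   "sigma": 0.06
  },
  {
   "name": "Cu(ADP)(OH)",
   "stoich": {
    "Cu": 1,
    "ADP": 1,
    "H": -1
   },
   "log_beta": -1.03,
   "sigma": 0.02
  },
  {
   "name": "Cu(Tyr)H3(ADP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "ADP": 1,
    "H": 3
   },
   "log_beta": 33.65,
   "sigma": 0.03
  },
  {
   "name": "Cu(Tyr)H2(ADP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "ADP": 1,
    "H": 2
   },
   "log_beta": 29.73,
   "sigma": 0.03
  },
  {
   "name": "Cu(Tyr)H(ADP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "ADP": 1,
    "H": 1
   },
   "log_beta": 25.11,
   "sigma": 0.02
  },
  {
   "name": "Cu(Tyr)(ADP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "ADP": 1
   },
   "log_beta": 19.01,
   "sigma": 0.02
  },
  {
   "name": "Cu(Tyr)(ADP)(OH)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "ADP": 1,
    "H": -1
   },
   "log_beta": 10.14,
   "sigma": 0.02
  },
  {
   "name": "Cu(Tyr)(ADP)(OH)2",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "ADP": 1,
    "H": -2
   },
   "log_beta": -0.27,
   "sigma": 0.02
  }
 ]
}
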