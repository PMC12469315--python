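{
 "name": "Cu_Tyr_ATP",
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
   "id": "ATP",
   "name": "adenosine-5'-triphosphate",
   "role": "ligand",
   "charge": -4
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
   "name": "H(ATP)",
   "stoich": {
    "ATP": 1,
    "H": 1
   },
   "log_beta": 6.5,
   "sigma": 0.01
  },
  {
   "name": "H2(ATP)",
   "stoich": {
    "ATP": 1,
    "H": 2
   },
   "log_beta": 10.88,
   "sigma": 0.02
  },
  {
   "name": "CuH(ATP)",
   "stoich": {
    "Cu": 1,
    "ATP": 1,
    "H": 1
   },
   "log_beta": 10.53,
   "sigma": 0.03
  },
  {
   "name": "Cu(ATP)",
   "stoich": {
    "Cu": 1,
    "ATP": 1
   },
   "log_beta": 6.63,
   "sigma": 0.02
  },
  {
   "name": "Cu(ATP)(OH)",
   "stoich": {
    "Cu": 1,
    "ATP": 1,
    "H": -1
   },
   "log_beta": -1.25,
   "sigma": 0.02
  },
  {
   "name": "Cu(Tyr)H4(ATP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "ATP": 1,
    "H": 4
   },
   "log_beta": 38.44,
   "sigma": 0.04
  },
  {
   "name": "Cu(Tyr)H3(ATP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "ATP": 1,
    "H": 3
   },
   "log_beta": 34.76,
   "sigma": 0.04
  },
  {
   "name": "Cu(Tyr)H2(ATP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "ATP": 1,
    "H": 2
   },
   "log_beta": 30.78,
   "sigma": 0.04
  },
  {
   "name": "Cu(Tyr)H(ATP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "ATP": 1,
    "H": 1
   },
   "log_beta": 24.51,
   "sigma": 0.02
  },
  {
   "name": "Cu(Tyr)(ATP)",
   "stoich": {
    "Cu": 1,
    "Tyr": 1,
    "ATP": 1
   },
   "log_beta": 14.56,
   "sigma": 0.07
  }
 ]
}
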