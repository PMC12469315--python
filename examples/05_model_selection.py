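"""Rank candidate species models against titration data.

Compares the true binary Cu/Tyr species set with a truncated set (missing
CuH2(Tyr)2) and a bloated set (a spurious CuH4(Tyr)2) on the same synthetic
curves.  The criterion mirrors refinement practice: keep the largest
species set that refines with low standard deviations and a low Sigma.
"""

import cuspec
from cuspec.model import SpeciationModel, SpeciesDef

FREE = ("CuH2(Tyr)", "CuH(Tyr)", "CuH2(Tyr)2", "CuH(Tyr)2")

study = cuspec.generate_study("Cu_Tyr", 3, cuspec.NoiseModel(0.005, seed=2),
                              n_points=100)
truth = study.truth
truncated = truth.drop_species(["CuH2(Tyr)2"])
bloated = SpeciationModel(
    truth.components,
    truth.species + (SpeciesDef("CuH4(Tyr)2", {"Cu": 1, "Tyr": 2, "H": 4}, 38.0),),
    truth.pKw, truth.temperature_C, truth.ionic_strength_M, "bloated")

candidates = [
    cuspec.RefinementSpec(truth, FREE, study.curves),
    cuspec.RefinementSpec(truncated,
                          tuple(n for n in FREE if n != "CuH2(Tyr)2"),
                          study.curves),
    cuspec.RefinementSpec(bloated, FREE + ("CuH4(Tyr)2",), study.curves),
]
for rank, (spec, res) in enumerate(cuspec.select_model(candidates), start=1):
    accepted = len(spec.free_parameters) - len(res.rejected_species)
    print(f"#{rank} {spec.model.name or 'truncated':<10} "
          f"accepted {accepted}/{len(spec.free_parameters)} species, "
          f"Sigma {res.Sigma_stat:9.4f}, "
          f"rejected {sorted(res.rejected_species) or '-'}")

# The true set ranks first; the spurious species is flagged (its constant
# is undetermined by the data), and dropping a real species inflates Sigma.
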